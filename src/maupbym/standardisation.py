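"""Indirect age standardisation: expected counts and incidence ratios.

Expected counts apply state-wide age-specific rates to each area's age
structure, E_i = sum_k y_k * pop_ik / pop_k, and the standardised incidence
ratio is SIR_i = y_i / E_i.  Because E is linear in the age-stratified
populations, expected counts computed at the finest level aggregate exactly
to those of any coarser level of a nested hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class StandardisationError(ValueError):
    pass


@dataclass
class StrataReference:
    """State-wide observed counts and populations per age stratum."""

    y_k: np.ndarray
    pop_k: np.ndarray

    def __post_init__(self) -> None:
        self.y_k = np.asarray(self.y_k, dtype=np.float64)
        self.pop_k = np.asarray(self.pop_k, dtype=np.float64)
        if self.y_k.shape != self.pop_k.shape or self.y_k.ndim != 1:
            raise StandardisationError("strata vectors must be aligned 1-D arrays")
        if np.any((self.pop_k == 0) & (self.y_k > 0)):
            raise StandardisationError("stratum with cases but zero population")

    @property
    def K(self) -> int:
        return self.y_k.size

    @property
    def rates(self) -> np.ndarray:
        """Per-stratum incidence rates y_k / pop_k (0 where the stratum is empty)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.pop_k > 0, self.y_k / self.pop_k, 0.0)
        return r


@dataclass
class OutcomeTable:
    """Per-area observed counts, expected counts and observed SIRs.

    ``sir`` is NaN where E_i = 0 (undefined ratio; such areas are rendered
    as missing on maps and excluded from model fits).
    """

    ids: list[str]
    y: np.ndarray
    E: np.ndarray
    sir: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.E = np.asarray(self.E, dtype=np.float64)
        if np.any(self.y < 0) or np.any(self.E < 0):
            raise StandardisationError("counts and expectations must be non-negative")
        if not (len(self.ids) == self.y.size == self.E.size):
            raise StandardisationError("outcome table columns misaligned")
        if self.sir is None:
            with np.errstate(invalid="ignore", divide="ignore"):
                self.sir = np.where(self.E > 0, self.y / self.E, np.nan)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area_id": self.ids, "y": self.y, "E": self.E, "sir": self.sir}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OutcomeTable":
        return cls(list(df["area_id"].astype(str)), df["y"].to_numpy(),
                   df["E"].to_numpy())

    def subset(self, keep: np.ndarray) -> "OutcomeTable":
        keep = np.asarray(keep, dtype=bool)
        return OutcomeTable(
            [a for a, k in zip(self.ids, keep) if k],
            self.y[keep], self.E[keep], self.sir[keep],
        )


def build_strata_reference(
    counts_by_stratum: np.ndarray, populations_by_stratum: np.ndarray
) -> StrataReference:
    """Sum per-area, per-stratum counts and populations to state level.

    Inputs are (n_areas, K) arrays (or 1-D per-stratum totals, passed
    through).
    """
    c = np.atleast_2d(np.asarray(counts_by_stratum, dtype=np.float64))
    p = np.atleast_2d(np.asarray(populations_by_stratum, dtype=np.float64))
    if c.shape[1] != p.shape[1]:
        raise StandardisationError("strata misaligned across counts and populations")
    return StrataReference(y_k=c.sum(axis=0), pop_k=p.sum(axis=0))


def expected_counts(pop_ik: np.ndarray, reference: StrataReference) -> np.ndarray:
    """E_i = sum_k y_k * pop_ik / pop_k."""
    pop_ik = np.asarray(pop_ik, dtype=np.float64)
    if pop_ik.ndim == 1:
        pop_ik = pop_ik[:, None]
    if pop_ik.shape[1] != reference.K:
        raise StandardisationError(
            f"area populations have {pop_ik.shape[1]} strata, reference has {reference.K}"
        )
    if np.any(pop_ik < 0):
        raise StandardisationError("populations must be non-negative")
    return pop_ik @ reference.rates


def compute_sir(ids, y: np.ndarray, E: np.ndarray) -> OutcomeTable:
    """Observed standardised incidence ratios y_i / E_i as an OutcomeTable."""
    return OutcomeTable(list(ids), np.asarray(y, float), np.asarray(E, float))


def read_strata_csv(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Long-format CSV (area_id, stratum, count, population) -> wide arrays."""
    df = pd.read_csv(path, dtype={"area_id": str})
    counts = df.pivot(index="area_id", columns="stratum", values="count")
    pops = df.pivot(index="area_id", columns="stratum", values="population")
    return list(counts.index), counts.to_numpy(float), pops.to_numpy(float)
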