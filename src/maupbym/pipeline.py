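"""End-to-end aggregation experiment: descriptives, SIRs, model fits, diagnostics.

Runs the full scale-effect study on one dataset: counts and covariates at
every level of the hierarchy, descriptive statistics per level, Moran's I of
the observed counts, BYM fits with and without the deprivation covariate at
each level, residual autocorrelation after each fit, and posterior summary
tables — with CSV/GeoJSON outputs and a structured run log.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bym import BYMChain, BYMConfig, PosteriorSummary, fit_bym, summarise
from .diagnostics import model_residuals, morans_i_test
from .geography import write_geojson
from .synthetic import ScenarioData

logger = logging.getLogger("maupbym")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage


@dataclass
class ExperimentResult:
    """All tables of one experiment run, in memory.

    ``table1`` holds per-level descriptive statistics of populations and
    counts; ``table2`` the Moran's I rows for observed counts and both
    residual sets; ``posterior_nocov``/``posterior_cov`` stack the per-level
    posterior summaries; ``summaries`` keeps the full summary objects and
    ``chains`` the raw draws keyed by (level, spec).
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    posterior_nocov: pd.DataFrame
    posterior_cov: pd.DataFrame
    summaries: dict[tuple[str, str], PosteriorSummary] = field(default_factory=dict)
    chains: dict[tuple[str, str], BYMChain] = field(default_factory=dict)
    fitted_levels: list[str] = field(default_factory=list)

    def n_fits(self) -> int:
        return len(self.chains)


def _summary_stats(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=np.float64)
    q25, q75 = np.percentile(x, [25, 75])
    return {
        "n": x.size,
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else np.nan,
        "min": float(x.min()),
        "median": float(np.median(x)),
        "iqr": float(q75 - q25),
        "max": float(x.max()),
    }


def descriptives(scenario: ScenarioData) -> pd.DataFrame:
    """Per-level summaries of population and counts (zero-population areas
    excluded), mirroring a registry-style descriptive table.  IQR is the
    75th minus the 25th percentile; SD is the n-1 sample standard deviation.
    """
    rows = []
    for level in scenario.levels:
        pop = scenario.hierarchy.total_population(level)
        keep = pop > 0
        if not keep.any():
            raise PipelineError("descriptives", ValueError(f"level {level} empty"))
        y = scenario.outcomes[level].y[keep]
        for variable, vals in (("population", pop[keep]), ("counts", y)):
            rows.append({"level": level, "variable": variable,
                         **_summary_stats(vals)})
    return pd.DataFrame(rows)


def _fit_seed(base_seed: int, tag: str) -> int:
    """Stable per-stage sub-seed derived from the run seed."""
    h = np.uint64(base_seed)
    for ch in tag:
        h = (h * np.uint64(1000003)) ^ np.uint64(ord(ch))
    return int(h % np.uint64(2**31 - 1))


def run_experiment(
    scenario: ScenarioData,
    bym_config: BYMConfig | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    levels_to_fit: list[str] | None = None,
    include_finest: bool = True,
    outdir=None,
    moran_style: str = "row",
    residual_kind: str = "pearson",
) -> ExperimentResult:
    """Full experiment: descriptives, Moran's I, 2 fits per level, summaries.

    ``include_finest=False`` skips the model fits (not the diagnostics) at
    the finest level, which dominates runtime; Moran's I of observed counts
    is always computed at every level.  Writes table1.csv, table2.csv,
    posterior_summary_{nocov,cov}.csv, maps_<level>.geojson and run.log when
    ``outdir`` is given.
    """
    t0 = time.time()
    bym_config = bym_config or BYMConfig()
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        fh = logging.FileHandler(f"{outdir}/run.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
        logger.setLevel(logging.INFO)
    logger.info(
        "experiment: seed=%d, chain=%d/%d/thin %d, permutations=%d",
        seed, bym_config.n_iter, bym_config.n_burnin, bym_config.thin,
        n_permutations,
    )

    try:
        table1 = descriptives(scenario)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("descriptives", exc) from exc

    if levels_to_fit is None:
        levels_to_fit = list(scenario.levels)
        if not include_finest:
            levels_to_fit = levels_to_fit[1:]

    table2_rows = []
    post_rows: dict[str, list[pd.DataFrame]] = {"nocov": [], "cov": []}
    summaries: dict[tuple[str, str], PosteriorSummary] = {}
    chains: dict[tuple[str, str], BYMChain] = {}
    map_frames: dict[str, pd.DataFrame] = {}

    for level in scenario.levels:
        pop = scenario.hierarchy.total_population(level)
        keep = (pop > 0) & (scenario.outcomes[level].E > 0)
        outcome = scenario.outcomes[level].subset(keep)
        adj = scenario.adjacency[level].subset(keep)
        cov = scenario.covariates[level].subset(keep)

        try:
            mt = morans_i_test(
                outcome.y, adj, style=moran_style,
                n_permutations=n_permutations,
                seed=_fit_seed(seed, f"moran-obs-{level}"),
            )
            table2_rows.append(
                {"level": level, "target": "observed", "statistic": mt.statistic,
                 "p_value": mt.p_value}
            )
            logger.info("moran observed %s: I=%.4f p=%.4g", level,
                        mt.statistic, mt.p_value)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"moran-observed-{level}", exc) from exc

        if level not in levels_to_fit:
            continue

        map_df = outcome.to_frame().rename(columns={"sir": "observed_sir"})
        for spec, use_cov in (("nocov", False), ("cov", True)):
            tag = f"fit-{level}-{spec}"
            try:
                cfg = bym_config.with_seed(_fit_seed(seed, tag))
                if not use_cov:
                    cfg = replace(cfg, include_covariate=False)
                chain = fit_bym(outcome, cov if use_cov else None, adj, cfg)
                summary = summarise(chain)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(tag, exc) from exc
            chains[(level, spec)] = chain
            summaries[(level, spec)] = summary
            gz = summary.params["geweke_z"].abs()
            flagged = gz[gz > 3].index.tolist()
            logger.info(
                "fit %s/%s: acc(alpha)=%.2f acc(u)=%.2f frac_spatial=%.3f%s",
                level, spec, chain.acceptance["alpha"],
                chain.acceptance["u_mean"], summary.fraction_spatial_variation,
                f" GEWEKE FLAGS {flagged}" if flagged else "",
            )
            if flagged:
                logger.warning("convergence flags (|z|>3) at %s/%s: %s",
                               level, spec, flagged)

            df = summary.to_frame()
            df.insert(0, "level", level)
            df["fraction_spatial_variation"] = summary.fraction_spatial_variation
            post_rows[spec].append(df)

            try:
                resid = model_residuals(outcome, summary.fitted_sir,
                                        kind=residual_kind)
                mt = morans_i_test(
                    resid, adj, style=moran_style,
                    n_permutations=n_permutations,
                    seed=_fit_seed(seed, f"moran-resid-{level}-{spec}"),
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"moran-residuals-{level}-{spec}", exc) from exc
            table2_rows.append(
                {"level": level, "target": f"resid_{spec}",
                 "statistic": mt.statistic, "p_value": mt.p_value}
            )
            map_df[f"fitted_sir_{spec}"] = summary.fitted_sir
        map_frames[level] = map_df

    result = ExperimentResult(
        table1=table1,
        table2=pd.DataFrame(table2_rows),
        posterior_nocov=(
            pd.concat(post_rows["nocov"], ignore_index=True)
            if post_rows["nocov"] else pd.DataFrame()
        ),
        posterior_cov=(
            pd.concat(post_rows["cov"], ignore_index=True)
            if post_rows["cov"] else pd.DataFrame()
        ),
        summaries=summaries,
        chains=chains,
        fitted_levels=[lv for lv in scenario.levels if lv in levels_to_fit],
    )

    if outdir is not None:
        result.table1.to_csv(f"{outdir}/table1.csv", index=False)
        result.table2.to_csv(f"{outdir}/table2.csv", index=False)
        result.posterior_nocov.to_csv(f"{outdir}/posterior_summary_nocov.csv",
                                      index=False)
        result.posterior_cov.to_csv(f"{outdir}/posterior_summary_cov.csv",
                                    index=False)
        for level, df in map_frames.items():
            geoms = scenario.hierarchy.geometry.get(level)
            if geoms is None:
                continue
            pop = scenario.hierarchy.total_population(level)
            keep = (pop > 0) & (scenario.outcomes[level].E > 0)
            kept_geoms = [g for g, k in zip(geoms, keep) if k]
            write_geojson(
                f"{outdir}/maps_{level}.geojson",
                list(df["area_id"]), kept_geoms, level,
                df.drop(columns=["area_id"]),
            )
        logger.info("experiment finished in %.1f s (%d fits)",
                    time.time() - t0, result.n_fits())
        for h in list(logger.handlers):
            if isinstance(h, logging.FileHandler):
                h.close()
                logger.removeHandler(h)
    return result
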