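"""Spatial-autocorrelation and MCMC convergence diagnostics.

Moran's I measures global spatial autocorrelation of a per-area variable
against a contiguity structure,

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,

with S0 the sum of all weights; inference is by random relabelling
(permutation) by default, with the classical normal approximation under the
randomisation assumption available as an alternative.  The Geweke score
compares early- and late-chain means of an MCMC trace on a standard-normal
scale, using autoregressive estimates of the spectral density at frequency
zero for the segment variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.regression.linear_model import yule_walker

from .geography import AdjacencyStructure


class DiagnosticsError(ValueError):
    pass


@dataclass
class MoranResult:
    statistic: float
    p_value: float
    n_permutations: int
    weight_style: str
    method: str = "permutation"
    expected: float = np.nan
    z_score: float = np.nan


@dataclass
class GewekeResult:
    z: float
    window_first: float
    window_last: float


def _style_weights(adj: AdjacencyStructure, style: str, keep: np.ndarray):
    w = adj.weights[keep][:, keep].tocsr()
    if style == "row":
        deg = np.asarray(w.sum(axis=1)).ravel()
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        w = w.multiply(inv[:, None]).tocsr()
    elif style != "binary":
        raise DiagnosticsError(f"unknown weight style {style!r}")
    return w


def _prepare(x, adj: AdjacencyStructure, style: str):
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (adj.n,):
        raise DiagnosticsError("x misaligned with adjacency")
    keep = ~adj.isolated
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} isolated area(s) from Moran's I",
            stacklevel=3,
        )
    x = x[keep]
    n = x.size
    if n < 3:
        raise DiagnosticsError("need at least 3 connected areas")
    if np.ptp(x) == 0:
        raise DiagnosticsError("x is constant: Moran's I undefined")
    w = _style_weights(adj, style, keep)
    s0 = w.sum()
    if s0 == 0:
        raise DiagnosticsError("all areas isolated")
    return x, w, s0, n


def morans_i(x, adjacency: AdjacencyStructure, style: str = "row") -> float:
    """Global Moran's I with binary or row-standardised weights."""
    x, w, s0, n = _prepare(x, adjacency, style)
    z = x - x.mean()
    return float(n / s0 * (z @ (w @ z)) / (z @ z))


def morans_i_test(
    x,
    adjacency: AdjacencyStructure,
    style: str = "row",
    n_permutations: int = 999,
    seed: int | None = None,
    method: str = "permutation",
) -> MoranResult:
    """Moran's I with a one-sided (greater) test against spatial randomness.

    The permutation test relabels x across areas uniformly at random and uses
    p = (1 + #{I_perm >= I_obs}) / (1 + n_permutations).  ``method='normal'``
    instead uses the moments of I under the randomisation assumption and a
    normal reference distribution (suitable when very small p-values must be
    resolved).
    """
    x, w, s0, n = _prepare(x, adjacency, style)
    z = x - x.mean()
    denom = z @ z
    i_obs = float(n / s0 * (z @ (w @ z)) / denom)
    e_i = -1.0 / (n - 1)

    if method == "permutation":
        if n_permutations < 99:
            raise DiagnosticsError("use at least 99 permutations")
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            zp = rng.permutation(z)
            i_perm = n / s0 * (zp @ (w @ zp)) / denom
            if i_perm >= i_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        return MoranResult(i_obs, float(p), n_permutations, style,
                           "permutation", e_i)
    if method == "normal":
        wd = w.toarray()
        s1 = 0.5 * np.sum((wd + wd.T) ** 2)
        s2 = np.sum((wd.sum(axis=1) + wd.sum(axis=0)) ** 2)
        b2 = n * np.sum(z**4) / denom**2
        num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
            (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
        )
        var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
        zscore = (i_obs - e_i) / np.sqrt(var_i)
        p = float(stats.norm.sf(zscore))
        return MoranResult(i_obs, p, 0, style, "normal", e_i, float(zscore))
    raise DiagnosticsError(f"unknown method {method!r}")


def model_residuals(outcome, fitted_sir: np.ndarray, kind: str = "pearson") -> np.ndarray:
    """Residuals against fitted counts E_i * fitted_sir_i.

    ``pearson`` (default): (y_i - fit_i)/sqrt(fit_i); ``response``: y_i - fit_i.
    """
    fitted_sir = np.asarray(fitted_sir, dtype=np.float64)
    fit = outcome.E * fitted_sir
    if kind == "response":
        return outcome.y - fit
    if kind == "pearson":
        if np.any(fit <= 0):
            raise DiagnosticsError("zero fitted count: Pearson residual undefined")
        return (outcome.y - fit) / np.sqrt(fit)
    raise DiagnosticsError(f"unknown residual kind {kind!r}")


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Yule-Walker AR fit.

    The AR order is chosen by AIC over 0..p_max; S(0) = sigma^2/(1 - sum
    phi)^2 so that var(mean) ~= S(0)/n accounts for autocorrelation.
    """
    n = x.size
    v = np.var(x, ddof=1)
    if v == 0:
        raise DiagnosticsError("constant segment: variance estimate degenerate")
    p_max = min(20, n // 10)
    best_aic, best = n * np.log(v), (np.array([]), np.sqrt(v))
    for p in range(1, p_max + 1):
        try:
            rho, sigma = yule_walker(x, order=p, method="mle")
        except np.linalg.LinAlgError:  # pragma: no cover - near-singular segment
            continue
        if sigma <= 0 or abs(1 - rho.sum()) < 1e-10:
            continue
        aic = n * np.log(sigma**2) + 2 * p
        if aic < best_aic:
            best_aic, best = aic, (rho, sigma)
    rho, sigma = best
    return float(sigma**2 / (1 - rho.sum()) ** 2)


def geweke(chain_values, frac1: float = 0.1, frac2: float = 0.5) -> GewekeResult:
    """Geweke convergence z-score for one ordered chain of draws.

    Compares the mean of the first ``frac1`` of the chain against the mean of
    the last ``frac2``; under convergence z is approximately standard normal.
    """
    x = np.asarray(chain_values, dtype=np.float64).ravel()
    if frac1 <= 0 or frac2 <= 0 or frac1 + frac2 > 1:
        raise DiagnosticsError("window fractions must be positive and non-overlapping")
    if x.size < 200:
        raise DiagnosticsError("need at least 200 draws for a Geweke score")
    n1 = int(np.floor(frac1 * x.size))
    n2 = int(np.floor(frac2 * x.size))
    if min(n1, n2) < 20:
        raise DiagnosticsError("segment too short for spectral variance estimation")
    a, b = x[:n1], x[-n2:]
    s0a, s0b = _spectrum0_ar(a), _spectrum0_ar(b)
    z = (a.mean() - b.mean()) / np.sqrt(s0a / n1 + s0b / n2)
    return GewekeResult(float(z), frac1, frac2)
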