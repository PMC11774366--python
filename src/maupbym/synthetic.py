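"""Synthetic nested-geography scenarios for the aggregation experiment.

Emulates, at desk scale, the situation the analysis is built for: a
five-level strictly nested areal hierarchy (mesh-block analogue up to an
SA4 analogue) over a square grid, right-skewed small-area populations with
an age structure, a spatially smooth deprivation score in quintiles, and
sparse disease counts generated at the third-finest (SA2-analogue) level
from the same log-linear model family the fitting stage assumes:

    Y_i ~ Poisson(E_i exp(alpha + x_i' beta + u_i + v_i)),

with u a proper-CAR Gaussian field (precision tau(D - rho A), rho < 1 so
the field can be sampled directly; the fitting stage still uses the
intrinsic limit) and v iid Gaussian noise.  Counts are then aggregated and
disaggregated to every other level through population-share correspondence
matrices, exactly as a real registry dataset would be.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from shapely.geometry import box

from .geography import (
    AdjacencyStructure,
    AreaHierarchy,
    CovariateTable,
    build_adjacency,
    membership_to_correspondence,
    transfer_counts,
    transfer_score,
)
from .standardisation import OutcomeTable, StrataReference, expected_counts

DEFAULT_LEVEL_NAMES = ("mesh", "sa1", "sa2", "sa3", "sa4")


class SyntheticError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Generative settings for one synthetic scenario.

    The default nesting 4096 -> 1024 -> 64 -> 16 -> 4 is a desk-scale
    analogue of the 67,047 / 11,507 / 507 / 82 / 19 Queensland hierarchy;
    ``total_cases_target`` = 1200 keeps the finest level in the sparse
    regime of roughly 0.3 cases per area.  Counts are generated at the
    third-finest level (the SA2 analogue, where registry data are released)
    and moved to all other levels afterwards.
    """

    nesting: tuple[int, ...] = (4096, 1024, 64, 16, 4)
    level_names: tuple[str, ...] | None = None
    K: int = 18
    total_cases_target: float = 1200.0
    alpha_true: float = 0.0
    beta_true: tuple[float, ...] = (-0.13, -0.23, -0.29, -0.46)
    sigma2_u_true: float = 0.1
    sigma2_v_true: float = 0.01
    rho: float = 0.95
    median_population: float = 82.0
    population_log_sd: float = 0.5
    zero_pop_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.nesting) < 3:
            raise SyntheticError("need at least 3 levels (counts are generated at the third-finest)")
        if any(a <= b for a, b in zip(self.nesting, self.nesting[1:])):
            raise SyntheticError("nesting must be strictly decreasing fine -> coarse")
        sides = []
        for n in self.nesting:
            s = int(round(np.sqrt(n)))
            if s * s != n:
                raise SyntheticError(f"level size {n} is not a perfect square")
            sides.append(s)
        for sf, sc in zip(sides, sides[1:]):
            if sf % sc:
                raise SyntheticError(
                    f"grid side {sf} does not divide into {sc} blocks"
                )
        if not 0 <= self.rho < 1:
            raise SyntheticError("rho must lie in [0, 1)")
        if self.level_names is None:
            if len(self.nesting) == len(DEFAULT_LEVEL_NAMES):
                self.level_names = DEFAULT_LEVEL_NAMES
            else:
                self.level_names = tuple(f"L{i}" for i in range(len(self.nesting)))
        if len(self.level_names) != len(self.nesting):
            raise SyntheticError("one level name per nesting entry")

    @property
    def generative_level(self) -> str:
        """Third-finest level: the native resolution of the simulated counts."""
        return self.level_names[2]


@dataclass
class ScenarioData:
    """Everything one synthetic scenario produces."""

    config: ScenarioConfig
    hierarchy: AreaHierarchy
    adjacency: dict[str, AdjacencyStructure]
    covariates: dict[str, CovariateTable]
    outcomes: dict[str, OutcomeTable]
    reference: StrataReference
    truth: dict = dc_field(default_factory=dict)

    @property
    def levels(self) -> list[str]:
        return self.hierarchy.levels


def _grid_side(n: int) -> int:
    return int(round(np.sqrt(n)))


def _grid_queen_edges(side: int, ids: list[str]) -> list[tuple[str, str]]:
    edges = []
    for r in range(side):
        for c in range(side):
            i = r * side + c
            for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < side and 0 <= cc < side:
                    edges.append((ids[i], ids[rr * side + cc]))
    return edges


def make_synthetic_hierarchy(
    config: ScenarioConfig, finest_population: np.ndarray | None = None
) -> tuple[AreaHierarchy, dict[str, AdjacencyStructure]]:
    """Square-grid hierarchy with queen adjacency and box geometries per level.

    The finest level is a sqrt(n) x sqrt(n) grid of unit squares; each
    coarser level merges equal square blocks of children, so every child has
    exactly one parent and coarser geometries are axis-aligned boxes too.
    """
    names = list(config.level_names)
    sides = [_grid_side(n) for n in config.nesting]
    ids = {
        name: [f"{name}_{k:05d}" for k in range(side * side)]
        for name, side in zip(names, sides)
    }
    membership: dict[tuple[str, str], dict[str, str]] = {}
    for (cn, cs), (pn, ps) in zip(zip(names, sides), zip(names[1:], sides[1:])):
        f = cs // ps
        m = {}
        for r in range(cs):
            for c in range(cs):
                m[ids[cn][r * cs + c]] = ids[pn][(r // f) * ps + (c // f)]
        membership[(cn, pn)] = m

    extent = float(sides[0])  # finest cells are unit squares
    geometry = {}
    for name, side in zip(names, sides):
        cell = extent / side
        geometry[name] = [
            box(c * cell, r * cell, (c + 1) * cell, (r + 1) * cell)
            for r in range(side)
            for c in range(side)
        ]

    if finest_population is None:
        finest_population = np.ones((config.nesting[0], 1))
    hierarchy = AreaHierarchy.from_finest(
        names, ids[names[0]], finest_population, membership, geometry
    )
    adjacency = {
        name: build_adjacency(ids[name], edge_list=_grid_queen_edges(side, ids[name]))
        for name, side in zip(names, sides)
    }
    return hierarchy, adjacency


def age_distribution(K: int) -> np.ndarray:
    """Stylised population age shares over K strata (gently declining)."""
    w = np.linspace(1.3, 0.4, K)
    return w / w.sum()


def incidence_schedule(K: int) -> np.ndarray:
    """Stylised relative incidence rising steeply with age (unnormalised)."""
    return np.exp(np.linspace(0.0, 4.0, K))


def simulate_population(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_finest, K) age-stratified populations for the finest level.

    Totals are log-normal around the configured median with a right skew;
    each total is split over age strata multinomially around a fixed share
    vector.  A small fraction of areas is zeroed out to exercise the
    zero-population exclusion rule downstream.
    """
    n = config.nesting[0]
    totals = rng.lognormal(np.log(config.median_population),
                           config.population_log_sd, size=n)
    totals = np.maximum(np.round(totals), 1).astype(np.int64)
    if config.zero_pop_fraction > 0:
        n_zero = int(round(config.zero_pop_fraction * n))
        if n_zero:
            totals[rng.choice(n, size=n_zero, replace=False)] = 0
    shares = age_distribution(config.K)
    pop = np.zeros((n, config.K))
    for i, tot in enumerate(totals):
        if tot:
            pop[i] = rng.multinomial(tot, shares)
    return pop


def _sample_proper_car(
    adj: AdjacencyStructure, sigma2: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(0, sigma2 * (D - rho A)^{-1}) and centre the result."""
    if sigma2 <= 0:
        raise SyntheticError("conditional variance must be positive")
    a = adj.weights.toarray()
    d = np.diag(a.sum(axis=1))
    q = (d - rho * a) / sigma2
    # isolated areas have zero degree: give them a proper N(0, sigma2) margin
    iso = np.flatnonzero(a.sum(axis=1) == 0)
    q[iso, iso] = 1.0 / sigma2
    L = np.linalg.cholesky(q)
    x = np.linalg.solve(L.T, rng.standard_normal(adj.n))
    return x - x.mean()


def simulate_covariate(
    hierarchy: AreaHierarchy,
    adjacency: dict[str, AdjacencyStructure],
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> dict[str, CovariateTable]:
    """IRSD-like deprivation scores, native at the SA2-analogue level.

    The native score is a large-scale planar gradient plus a proper-CAR
    field, scaled to an index around 1000; it is copied down to finer levels
    and population-weight averaged up to coarser ones, then cut into
    population-weighted quintiles separately at every level.
    """
    gen = config.generative_level
    side = _grid_side(hierarchy.n_areas(gen))
    rr, cc = np.divmod(np.arange(side * side), side)
    gradient = (rr + cc) / (2 * (side - 1)) - 0.5
    car = _sample_proper_car(adjacency[gen], 1.0, config.rho, rng)
    car = car / max(car.std(), 1e-12)
    score = 1000.0 + 80.0 * gradient + 40.0 * car

    gi = hierarchy.level_index(gen)
    out: dict[str, CovariateTable] = {}
    for level in hierarchy.levels:
        li = hierarchy.level_index(level)
        pops = hierarchy.total_population(level)
        if li == gi:
            level_score = score
        else:
            corr = membership_to_correspondence(hierarchy, gen, level)
            level_score = transfer_score(
                score, hierarchy.total_population(gen), corr,
                source_is_finer=gi < li,
            )
        out[level] = CovariateTable.from_scores(
            hierarchy.ids[level], level_score, pops
        )
    return out


def simulate_counts(
    hierarchy: AreaHierarchy,
    adjacency: dict[str, AdjacencyStructure],
    covariates: dict[str, CovariateTable],
    config: ScenarioConfig,
    rng: np.random.Generator,
    count_mode: str = "fractional",
) -> tuple[dict[str, OutcomeTable], StrataReference, dict]:
    """Sparse counts at the generative level, transferred to every level.

    Expected counts come from an age-incidence schedule scaled so that the
    state-wide expectation equals ``total_cases_target``; they are computed
    at the finest level and aggregated exactly (the formula is linear in the
    age-stratified populations).  Counts are Poisson draws at the generative
    level and moved elsewhere through correspondence matrices — fractional
    by default, or multinomially integerised with ``count_mode='multinomial'``.
    """
    finest = hierarchy.levels[0]
    gen = config.generative_level
    gi = hierarchy.level_index(gen)

    pop_ik = hierarchy.population[finest]
    pop_k = pop_ik.sum(axis=0)
    base = incidence_schedule(config.K)
    scale = config.total_cases_target / float(pop_k @ base)
    rates = base * scale
    reference = StrataReference(y_k=rates * pop_k, pop_k=pop_k)
    E_fine = expected_counts(pop_ik, reference)

    E_by_level = {finest: E_fine}
    for level in hierarchy.levels[1:]:
        corr = membership_to_correspondence(hierarchy, finest, level)
        E_by_level[level] = transfer_counts(E_fine, corr)

    u = _sample_proper_car(adjacency[gen], config.sigma2_u_true, config.rho, rng)
    v = rng.normal(0.0, np.sqrt(config.sigma2_v_true), size=hierarchy.n_areas(gen))
    x = covariates[gen].design_matrix()
    beta = np.asarray(config.beta_true, dtype=np.float64)
    mu = config.alpha_true + x @ beta + u + v
    y_gen = rng.poisson(E_by_level[gen] * np.exp(mu)).astype(np.float64)

    outcomes: dict[str, OutcomeTable] = {}
    for level in hierarchy.levels:
        li = hierarchy.level_index(level)
        if li == gi:
            y_level = y_gen
        else:
            corr = membership_to_correspondence(hierarchy, gen, level)
            y_level = transfer_counts(
                y_gen, corr,
                mode=count_mode if li < gi else "fractional",
                rng=rng,
            )
            if li > gi:  # aggregation of integers stays integral
                y_level = np.round(y_level, 9)
        outcomes[level] = OutcomeTable(hierarchy.ids[level], y_level, E_by_level[level])

    truth = {
        "alpha": config.alpha_true, "beta": beta, "u": u, "v": v, "mu": mu,
        "level": gen,
    }
    return outcomes, reference, truth


def simulate_scenario(
    config: ScenarioConfig, count_mode: str = "fractional"
) -> ScenarioData:
    """Generate a full scenario; byte-identical for identical config + seed."""
    rng = np.random.default_rng(config.seed)
    pop = simulate_population(config, rng)
    hierarchy, adjacency = make_synthetic_hierarchy(config, pop)
    covariates = simulate_covariate(hierarchy, adjacency, config, rng)
    outcomes, reference, truth = simulate_counts(
        hierarchy, adjacency, covariates, config, rng, count_mode=count_mode
    )
    return ScenarioData(
        config=config,
        hierarchy=hierarchy,
        adjacency=adjacency,
        covariates=covariates,
        outcomes=outcomes,
        reference=reference,
        truth=truth,
    )
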