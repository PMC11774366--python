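"""Nested areal hierarchies, contiguity structures and cross-level transfer.

Australian-style statistical geographies are strictly nested: every unit of a
fine level (e.g. a mesh block) lies wholly within a single unit of each coarser
level (SA1 ... SA4).  This module represents such a hierarchy, derives
neighbourhood (contiguity) structures from polygons or edge lists, and moves
counts and area-level index scores between aggregation levels through
population-weighted correspondence matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely import STRtree
from shapely.geometry import mapping, shape


class GeographyError(ValueError):
    """Raised for inconsistent hierarchy, adjacency or correspondence inputs."""


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------


@dataclass
class AdjacencyStructure:
    """Symmetric binary contiguity structure over one level's areas.

    ``weights`` is a sparse 0/1 matrix with zero diagonal (w_ij = 1 iff areas
    i and j are neighbours).  ``components`` labels graph connected
    components; isolated areas form singleton components.
    """

    ids: list[str]
    weights: sp.csr_matrix
    components: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = sp.csr_matrix(self.weights)
        w.data = np.ones_like(w.data, dtype=np.float64)
        if (w != w.T).nnz:
            raise GeographyError("adjacency weights must be symmetric")
        if w.diagonal().any():
            raise GeographyError("adjacency weights must have a zero diagonal")
        self.weights = w
        if self.components is None:
            _, labels = connected_components(w, directed=False)
            self.components = labels
        self.components = np.asarray(self.components)
        if len(self.ids) != w.shape[0] or len(self.components) != w.shape[0]:
            raise GeographyError("ids / weights / components sizes disagree")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1 if self.n else 0

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()

    @property
    def isolated(self) -> np.ndarray:
        """Boolean mask of areas with no neighbour."""
        return self.degrees == 0

    def edge_list(self) -> list[tuple[str, str]]:
        coo = sp.triu(self.weights).tocoo()
        return [(self.ids[i], self.ids[j]) for i, j in zip(coo.row, coo.col)]

    def subset(self, keep: np.ndarray) -> "AdjacencyStructure":
        """Restrict to a boolean mask of areas, recomputing components."""
        keep = np.asarray(keep, dtype=bool)
        ids = [a for a, k in zip(self.ids, keep) if k]
        w = self.weights[keep][:, keep].tocsr()
        return AdjacencyStructure(ids=ids, weights=w, components=None)


def build_adjacency(
    ids,
    geometries=None,
    edge_list=None,
    rule: str = "queen",
) -> AdjacencyStructure:
    """Build a binary contiguity structure from polygons or an edge list.

    With polygons, two areas are neighbours under ``rule='queen'`` iff their
    boundaries share at least one point (a corner suffices); under ``'rook'``
    a shared boundary segment of positive length is required.  Isolated areas
    are permitted and flagged with a warning.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise GeographyError("area ids must be unique within a level")
    n = len(ids)
    pos = {a: k for k, a in enumerate(ids)}

    rows: list[int] = []
    cols: list[int] = []
    if edge_list is not None:
        for a, b in edge_list:
            if a not in pos or b not in pos:
                raise GeographyError(f"edge references unknown id: ({a}, {b})")
            if a == b:
                raise GeographyError(f"self-pair in edge list: {a}")
            rows += [pos[a], pos[b]]
            cols += [pos[b], pos[a]]
    elif geometries is not None:
        geometries = list(geometries)
        if len(geometries) != n:
            raise GeographyError("one geometry required per area id")
        tree = STRtree(geometries)
        for i, geom in enumerate(geometries):
            for j in tree.query(geom, predicate="intersects"):
                j = int(j)
                if j <= i:
                    continue
                inter = geom.intersection(geometries[j])
                if inter.is_empty:
                    continue
                if rule == "rook" and inter.length == 0.0:
                    continue  # point contact only
                rows += [i, j]
                cols += [j, i]
    else:
        raise GeographyError("provide either geometries or an edge list")

    w = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    w.data = np.minimum(w.data, 1.0)  # collapse duplicate edges
    adj = AdjacencyStructure(ids=ids, weights=w)
    if adj.isolated.any():
        iso = [ids[k] for k in np.flatnonzero(adj.isolated)]
        warnings.warn(f"{len(iso)} isolated area(s): {iso[:5]}...", stacklevel=2)
    return adj


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------


@dataclass
class AreaHierarchy:
    """Ordered nested levels of areal units with memberships and populations.

    ``levels`` runs fine -> coarse.  ``ids[level]`` lists that level's area
    ids; ``population[level]`` is an (n_areas, K) array of person-counts by
    age stratum.  ``membership[(child_level, parent_level)]`` maps each child
    id to its unique parent id for adjacent level pairs; coarser-level
    populations are derived by exact summation over children.
    """

    levels: list[str]
    ids: dict[str, list[str]]
    population: dict[str, np.ndarray]
    membership: dict[tuple[str, str], dict[str, str]]
    geometry: dict[str, list] = field(default_factory=dict)

    @classmethod
    def from_finest(
        cls,
        levels: list[str],
        finest_ids: list[str],
        finest_population: np.ndarray,
        membership: dict[tuple[str, str], dict[str, str]],
        geometry: dict[str, list] | None = None,
    ) -> "AreaHierarchy":
        """Build a hierarchy from the finest level up, summing populations."""
        finest_population = np.asarray(finest_population, dtype=np.float64)
        if finest_population.ndim == 1:
            finest_population = finest_population[:, None]
        if np.any(~np.isfinite(finest_population)) or np.any(finest_population < 0):
            raise GeographyError("populations must be finite and non-negative")
        ids = {levels[0]: list(finest_ids)}
        population = {levels[0]: finest_population}
        for child, parent in zip(levels[:-1], levels[1:]):
            key = (child, parent)
            if key not in membership:
                raise GeographyError(f"missing membership map for {key}")
            mapping_ = membership[key]
            missing = [c for c in ids[child] if c not in mapping_]
            if missing:
                raise GeographyError(
                    f"children without a parent at {child}->{parent}: {missing[:5]}"
                )
            parent_ids = sorted(set(mapping_.values()))
            idx = {p: k for k, p in enumerate(parent_ids)}
            pop = np.zeros((len(parent_ids), finest_population.shape[1]))
            for c, p in zip(ids[child], population[child]):
                pop[idx[mapping_[c]]] += p
            ids[parent] = parent_ids
            population[parent] = pop
        return cls(
            levels=list(levels),
            ids=ids,
            population=population,
            membership=dict(membership),
            geometry=geometry or {},
        )

    def n_areas(self, level: str) -> int:
        return len(self.ids[level])

    def total_population(self, level: str) -> np.ndarray:
        """Per-area total population (summed over age strata)."""
        return self.population[level].sum(axis=1)

    def level_index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError as exc:
            raise GeographyError(f"unknown level {level!r}") from exc

    def parent_map(self, fine: str, coarse: str) -> dict[str, str]:
        """Child -> ancestor map across any number of intermediate levels."""
        i, j = self.level_index(fine), self.level_index(coarse)
        if i >= j:
            raise GeographyError(f"{fine!r} is not finer than {coarse!r}")
        out = {a: a for a in self.ids[fine]}
        for child, parent in zip(self.levels[i:j], self.levels[i + 1 : j + 1]):
            step = self.membership[(child, parent)]
            out = {a: step[p] for a, p in out.items()}
        return out


# ---------------------------------------------------------------------------
# correspondence and transfer
# ---------------------------------------------------------------------------


@dataclass
class CorrespondenceMatrix:
    """Population-share weights mapping one level's areas onto another's.

    Rows are indexed by source areas and sum to one: fine -> coarse rows are
    unit vectors on the unique ancestor; coarse -> fine rows carry descendant
    population shares.
    """

    source_level: str
    target_level: str
    source_ids: list[str]
    target_ids: list[str]
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        w = sp.csr_matrix(self.weights, dtype=np.float64)
        if w.shape != (len(self.source_ids), len(self.target_ids)):
            raise GeographyError("correspondence weight shape mismatch")
        if w.nnz and (w.data.min() < -1e-12 or w.data.max() > 1 + 1e-9):
            raise GeographyError("correspondence weights must lie in [0, 1]")
        rows = np.asarray(w.sum(axis=1)).ravel()
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise GeographyError("correspondence rows must sum to 1")
        self.weights = w

    def compose(self, other: "CorrespondenceMatrix") -> "CorrespondenceMatrix":
        """Chain two correspondences (matrix product of the share matrices)."""
        if self.target_level != other.source_level or self.target_ids != other.source_ids:
            raise GeographyError("correspondences are not chainable")
        return CorrespondenceMatrix(
            source_level=self.source_level,
            target_level=other.target_level,
            source_ids=self.source_ids,
            target_ids=other.target_ids,
            weights=(self.weights @ other.weights).tocsr(),
        )

    def to_frame(self) -> pd.DataFrame:
        coo = self.weights.tocoo()
        return pd.DataFrame(
            {
                "source_id": [self.source_ids[i] for i in coo.row],
                "target_id": [self.target_ids[j] for j in coo.col],
                "weight": coo.data,
            }
        )


def membership_to_correspondence(
    hierarchy: AreaHierarchy, source_level: str, target_level: str
) -> CorrespondenceMatrix:
    """Correspondence between any two hierarchy levels.

    Fine -> coarse rows place weight 1 on the unique ancestor (aggregation is
    exact summation).  Coarse -> fine rows distribute by descendant total
    population share; a zero-population source area makes the shares
    undefined and raises.
    """
    si, ti = hierarchy.level_index(source_level), hierarchy.level_index(target_level)
    if si == ti:
        n = hierarchy.n_areas(source_level)
        return CorrespondenceMatrix(
            source_level, target_level,
            hierarchy.ids[source_level], hierarchy.ids[target_level],
            sp.identity(n, format="csr"),
        )
    fine = source_level if si < ti else target_level
    coarse = target_level if si < ti else source_level
    pmap = hierarchy.parent_map(fine, coarse)
    fine_ids = hierarchy.ids[fine]
    coarse_ids = hierarchy.ids[coarse]
    cidx = {a: k for k, a in enumerate(coarse_ids)}
    rows = np.arange(len(fine_ids))
    cols = np.array([cidx[pmap[a]] for a in fine_ids])
    if si < ti:  # aggregation: unit rows on the ancestor
        w = sp.csr_matrix(
            (np.ones(len(fine_ids)), (rows, cols)),
            shape=(len(fine_ids), len(coarse_ids)),
        )
        return CorrespondenceMatrix(source_level, target_level, fine_ids, coarse_ids, w)
    # disaggregation: population shares of descendants
    fine_pop = hierarchy.total_population(fine)
    coarse_pop = hierarchy.total_population(coarse)
    zero_parents = coarse_pop == 0
    if np.any(zero_parents):
        bad = [coarse_ids[k] for k in np.flatnonzero(zero_parents)]
        raise GeographyError(
            f"zero total population in source area(s) {bad[:5]}: shares undefined"
        )
    shares = fine_pop / coarse_pop[cols]
    w = sp.csr_matrix(
        (shares, (cols, rows)), shape=(len(coarse_ids), len(fine_ids))
    )
    return CorrespondenceMatrix(source_level, target_level, coarse_ids, fine_ids, w)


def transfer_counts(
    counts: np.ndarray,
    corr: CorrespondenceMatrix,
    mode: str = "fractional",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Move a per-area count vector across levels, conserving the grand total.

    Fractional mode computes target_j = sum_i counts_i * w_ij, so
    disaggregated counts may be non-integer.  Multinomial mode instead
    allocates each source area's integer count at random with the row shares
    (requires ``rng``); totals are then conserved exactly in integers.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (len(corr.source_ids),):
        raise GeographyError("counts misaligned with correspondence source areas")
    if np.any(~np.isfinite(counts)) or np.any(counts < 0):
        raise GeographyError("counts must be finite and non-negative")
    if mode == "fractional":
        return np.asarray(corr.weights.T @ counts)
    if mode == "multinomial":
        if rng is None:
            raise GeographyError("multinomial mode requires an rng")
        if np.any(counts != np.round(counts)):
            raise GeographyError("multinomial mode requires integer counts")
        out = np.zeros(len(corr.target_ids))
        w = corr.weights
        for i in range(w.shape[0]):
            c = int(counts[i])
            if c == 0:
                continue
            sl = slice(w.indptr[i], w.indptr[i + 1])
            p = w.data[sl] / w.data[sl].sum()
            out[w.indices[sl]] += rng.multinomial(c, p)
        return out
    raise GeographyError(f"unknown transfer mode {mode!r}")


def transfer_score(
    scores: np.ndarray,
    populations: np.ndarray,
    corr: CorrespondenceMatrix,
    source_is_finer: bool | None = None,
) -> np.ndarray:
    """Move an area-level index score (not a mass) across levels.

    Aggregating (fine -> coarse) takes the population-weighted mean of the
    constituent scores; disaggregating copies the ancestor's score to every
    descendant unchanged.  ``populations`` are per-source-area totals, used
    only when aggregating.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(corr.source_ids),):
        raise GeographyError("scores misaligned with correspondence source areas")
    w = corr.weights
    if source_is_finer is None:
        # fine->coarse correspondences have one-hot rows of weight exactly 1
        row_nnz = np.diff(w.indptr)
        source_is_finer = bool(np.all(row_nnz == 1) and np.allclose(w.data, 1.0))
    if source_is_finer:
        populations = np.asarray(populations, dtype=np.float64)
        num = w.T @ (populations * scores)
        den = w.T @ populations
        if np.any(den <= 0):
            raise GeographyError("zero aggregate population in a target area")
        return num / den
    # each fine target has a unique ancestor: pick the source with w > 0
    coo = w.tocoo()
    out = np.full(len(corr.target_ids), np.nan)
    out[coo.col] = scores[coo.row]
    if np.any(np.isnan(out)):
        raise GeographyError("some target areas receive no score")
    return out


def assign_quintiles(scores: np.ndarray, populations: np.ndarray) -> np.ndarray:
    """Population-weighted quintile labels 1..5, 1 = most disadvantaged.

    Areas are sorted by score ascending and cut at cumulative-population
    fractions 0.2/0.4/0.6/0.8; lower score means lower quintile.  Tied scores
    share the quintile of the first tied element.  With fewer than 5 areas
    some quintiles are necessarily empty (warned, as for a 4-area coarsest
    level).
    """
    scores = np.asarray(scores, dtype=np.float64)
    populations = np.asarray(populations, dtype=np.float64)
    if scores.size < 2:
        raise GeographyError("need at least 2 areas to form quintiles")
    if scores.size < 5:
        warnings.warn(
            f"only {scores.size} areas: some quintiles will be empty",
            stacklevel=2,
        )
    if np.any(~np.isfinite(scores)):
        raise GeographyError("scores must be finite")
    if np.ptp(scores) == 0:
        raise GeographyError("all scores identical: degenerate covariate")
    order = np.argsort(scores, kind="stable")
    total = populations.sum()
    if total <= 0:
        raise GeographyError("total population must be positive")
    cum_before = np.concatenate([[0.0], np.cumsum(populations[order])[:-1]])
    q_sorted = np.minimum((cum_before / total * 5).astype(int), 4) + 1
    # ties share the first tied element's quintile
    s_sorted = scores[order]
    for k in range(1, len(q_sorted)):
        if s_sorted[k] == s_sorted[k - 1]:
            q_sorted[k] = q_sorted[k - 1]
    out = np.empty(len(scores), dtype=int)
    out[order] = q_sorted
    return out


@dataclass
class CovariateTable:
    """Per-area deprivation index scores with quintile categories.

    Quintile 1 (lowest scores) is the most disadvantaged and serves as the
    reference category in regression design matrices.
    """

    ids: list[str]
    score: np.ndarray
    quintile: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=np.float64)
        self.quintile = np.asarray(self.quintile, dtype=int)
        if not (len(self.ids) == len(self.score) == len(self.quintile)):
            raise GeographyError("covariate table columns misaligned")
        if self.quintile.size and not np.all((self.quintile >= 1) & (self.quintile <= 5)):
            raise GeographyError("quintiles must lie in 1..5")

    @classmethod
    def from_scores(cls, ids, scores, populations) -> "CovariateTable":
        return cls(list(ids), np.asarray(scores, float),
                   assign_quintiles(scores, populations))

    def design_matrix(self) -> np.ndarray:
        """(n, 4) indicators for quintiles 2..5; quintile 1 is the reference."""
        x = np.zeros((len(self.ids), 4))
        for j in range(2, 6):
            x[:, j - 2] = self.quintile == j
        return x

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area_id": self.ids, "score": self.score, "quintile": self.quintile}
        )

    def subset(self, keep: np.ndarray) -> "CovariateTable":
        keep = np.asarray(keep, dtype=bool)
        return CovariateTable(
            [a for a, k in zip(self.ids, keep) if k],
            self.score[keep], self.quintile[keep],
        )


# ---------------------------------------------------------------------------
# plain-text interchange formats
# ---------------------------------------------------------------------------


def read_edge_list(path) -> list[tuple[str, str]]:
    """One tab-separated ``id_i<TAB>id_j`` pair per line; '#' comments allowed."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")
            edges.append((a, b))
    return edges


def write_edge_list(adj: AdjacencyStructure, path) -> None:
    with open(path, "w") as fh:
        for a, b in adj.edge_list():
            fh.write(f"{a}\t{b}\n")


def read_geojson(path) -> tuple[list[str], list, list[str]]:
    """Return (area ids, shapely geometries, levels) from a FeatureCollection."""
    with open(path) as fh:
        fc = json.load(fh)
    ids, geoms, levels = [], [], []
    for feat in fc["features"]:
        ids.append(str(feat["properties"]["area_id"]))
        levels.append(str(feat["properties"].get("level", "")))
        geoms.append(shape(feat["geometry"]))
    return ids, geoms, levels


def write_geojson(path, ids, geometries, level: str, properties: pd.DataFrame | None = None) -> None:
    """Write a FeatureCollection with ``area_id``/``level`` plus extra columns."""
    feats = []
    for k, (a, g) in enumerate(zip(ids, geometries)):
        props = {"area_id": a, "level": level}
        if properties is not None:
            for col in properties.columns:
                val = properties.iloc[k][col]
                props[col] = None if pd.isna(val) else (
                    float(val) if isinstance(val, (np.floating, float)) else
                    int(val) if isinstance(val, (np.integer, int)) else val
                )
        feats.append(
            {"type": "Feature", "geometry": mapping(g), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_membership_csv(path) -> dict[tuple[str, str], dict[str, str]]:
    """CSV with columns child_id,parent_id,child_level,parent_level."""
    df = pd.read_csv(path, dtype=str)
    out: dict[tuple[str, str], dict[str, str]] = {}
    for (cl, pl), grp in df.groupby(["child_level", "parent_level"]):
        out[(cl, pl)] = dict(zip(grp["child_id"], grp["parent_id"]))
    return out


def write_membership_csv(hierarchy: AreaHierarchy, path) -> None:
    rows = []
    for (cl, pl), mapping_ in hierarchy.membership.items():
        for c, p in mapping_.items():
            rows.append((c, p, cl, pl))
    pd.DataFrame(
        rows, columns=["child_id", "parent_id", "child_level", "parent_level"]
    ).to_csv(path, index=False)


def read_correspondence_csv(path, source_level: str, target_level: str) -> CorrespondenceMatrix:
    """CSV with columns source_id,target_id,weight (rows must sum to 1)."""
    df = pd.read_csv(path, dtype={"source_id": str, "target_id": str})
    source_ids = sorted(df["source_id"].unique())
    target_ids = sorted(df["target_id"].unique())
    si = {a: k for k, a in enumerate(source_ids)}
    ti = {a: k for k, a in enumerate(target_ids)}
    w = sp.csr_matrix(
        (
            df["weight"].to_numpy(float),
            (df["source_id"].map(si), df["target_id"].map(ti)),
        ),
        shape=(len(source_ids), len(target_ids)),
    )
    return CorrespondenceMatrix(source_level, target_level, source_ids, target_ids, w)
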