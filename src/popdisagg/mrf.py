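"""Markov-random-field disaggregation with Iterated Conditional Modes.

Population values on the active cells (those with at least one
building) are chosen to minimize

    E(p) = sum_i sum_{k in Q_i} |p_i - p_k|
         + lambda * sum_j |c_j - sum_{k in A_j} p_k|

where Q_i are the k nearest neighbours of cell i in a z-normalized
covariate feature space (the double sum is directed: each ordered pair
counted once). The first term pulls cells with similar covariates
toward similar populations, the second pulls region sums toward the
census. Minimization is coordinate descent (ICM): cells are visited in
a seeded random order and each is moved to the best of
``{p_i, 1.01 * p_i, 0.99 * p_i}`` (multiplicative +/-1% steps); the
energy trace is non-increasing by construction. Cells starting at zero
stay at zero — multiplicative steps cannot leave it — which is why the
recommended initialization is building-count disaggregation (positive
on every active cell of a populated region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import rng_for
from .grids import (
    BuildingCountMap,
    CensusTable,
    CovariateStack,
    PopulationMap,
    RegionMap,
    ValidationError,
)

__all__ = ["MRFConfig", "FeatureGraph", "build_knn_graph", "mrf_energy", "icm_disaggregate"]

_EXACT_KNN_MAX = 4000


@dataclass
class MRFConfig:
    """MRF hyper-parameters; lambda = 1 balances smoothness vs census fit."""

    k_neighbors: int = 10
    lam: float = 1.0
    step_fraction: float = 0.01
    max_sweeps: int = 100
    feature_channels: tuple = ("building_count", "mean_building_area", "nightlight")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if self.step_fraction <= 0:
            raise ValidationError("step_fraction must be > 0")
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")


@dataclass
class FeatureGraph:
    """kNN graph over active cells in normalized feature space."""

    cell_index: np.ndarray  # flat grid indices of the N active cells
    neighbors: np.ndarray  # (N, k) indices into cell_index order
    features: np.ndarray  # (N, d) z-normalized features used
    approximate_ties: bool = False

    def __post_init__(self) -> None:
        n, k = self.neighbors.shape
        if n != len(self.cell_index):
            raise ValidationError("neighbor table does not match cell index")
        if (self.neighbors == np.arange(n)[:, None]).any():
            raise ValidationError("a cell lists itself as neighbor")

    @property
    def n_cells(self) -> int:
        return len(self.cell_index)

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]


def build_knn_graph(
    stack: CovariateStack, buildings: BuildingCountMap, cfg: MRFConfig
) -> FeatureGraph:
    """Exact Euclidean kNN over active cells (ties broken by lowest index).

    Features are the configured channels, z-normalized over active
    cells; the name ``"building_count"`` draws from the building map
    instead of the stack. Above a few thousand active cells the exact
    all-pairs scan is replaced by a tree-based search whose tie order
    is not guaranteed (``approximate_ties=True``).
    """
    stack.grid.require_compatible(buildings.grid, "buildings")
    cell_index = np.flatnonzero(buildings.active_mask.ravel())
    n = len(cell_index)
    if n < cfg.k_neighbors + 1:
        raise ValidationError(
            f"{n} active cells but k={cfg.k_neighbors} needs at least k+1"
        )
    cols = []
    for name in cfg.feature_channels:
        if name == "building_count":
            cols.append(buildings.counts.ravel()[cell_index].astype(np.float64))
        else:
            cols.append(stack.channel(name).ravel()[cell_index])
    feats = np.column_stack(cols)
    feats = (feats - feats.mean(axis=0)) / np.maximum(feats.std(axis=0), 1e-12)

    k = cfg.k_neighbors
    if n <= _EXACT_KNN_MAX:
        d2 = ((feats[:, None, :] - feats[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        order = np.argsort(d2, axis=1, kind="stable")  # stable -> lowest-index ties
        neighbors = order[:, :k]
        approx = False
    else:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(feats)
        _, idx = nn.kneighbors(feats)
        neighbors = np.empty((n, k), dtype=np.int64)
        for i in range(n):
            row = idx[i][idx[i] != i][:k]
            neighbors[i] = row
        approx = True
    return FeatureGraph(cell_index, neighbors, feats, approximate_ties=approx)


def _region_index(regions: RegionMap, census: CensusTable, cell_index: np.ndarray):
    ids = regions.ids.ravel()[cell_index]
    region_ids = np.unique(ids[ids > 0])
    for rid in region_ids:
        if int(rid) not in census.entries:
            raise KeyError(f"region {int(rid)} missing from census")
    lookup = {int(r): i for i, r in enumerate(region_ids)}
    region_of = np.array([lookup.get(int(r), -1) for r in ids], dtype=np.int64)
    targets = census.counts_for(region_ids)
    return region_of, targets


def mrf_energy(
    p: np.ndarray,
    graph: FeatureGraph,
    regions: RegionMap,
    census: CensusTable,
    lam: float = 1.0,
) -> float:
    """Evaluate the energy for values ``p`` on the graph's active cells."""
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (graph.n_cells,):
        raise ValidationError(f"p has shape {p.shape}, expected ({graph.n_cells},)")
    smooth = np.abs(p[:, None] - p[graph.neighbors]).sum()
    region_of, targets = _region_index(regions, census, graph.cell_index)
    sums = np.bincount(region_of[region_of >= 0], weights=p[region_of >= 0],
                       minlength=len(targets))
    census_term = np.abs(targets - sums).sum()
    return float(smooth + lam * census_term)


def icm_disaggregate(
    init: PopulationMap,
    graph: FeatureGraph,
    regions: RegionMap,
    census: CensusTable,
    cfg: MRFConfig,
) -> tuple[PopulationMap, list[float]]:
    """Coordinate-descent minimization with multiplicative +/-1% moves.

    Returns the refined map and the per-sweep energy trace (first entry
    is the initial energy). Stops at ``max_sweeps`` or when a full
    sweep accepts no move.
    """
    init.grid.require_compatible(regions.grid, "regions")
    p = init.values.ravel()[graph.cell_index].astype(np.float64)
    if not np.all(np.isfinite(p)):
        raise ValidationError("non-finite initialization")

    region_of, targets = _region_index(regions, census, graph.cell_index)
    n, k = graph.n_cells, graph.k
    # reverse adjacency: for each cell, who lists it as neighbor
    src = np.repeat(np.arange(n), k)
    dst = graph.neighbors.ravel()
    order_rev = np.argsort(dst, kind="stable")
    rev_sorted_src = src[order_rev]
    rev_starts = np.searchsorted(dst[order_rev], np.arange(n + 1))

    region_sums = np.bincount(region_of[region_of >= 0], weights=p[region_of >= 0],
                              minlength=len(targets))
    lam = cfg.lam
    up, down = 1.0 + cfg.step_fraction, 1.0 - cfg.step_fraction

    def local_energy(i: int, pi: float) -> float:
        e = np.abs(pi - p[graph.neighbors[i]]).sum()
        rs = rev_sorted_src[rev_starts[i] : rev_starts[i + 1]]
        if len(rs):
            e += np.abs(p[rs] - pi).sum()
        r = region_of[i]
        if r >= 0:
            e += lam * abs(targets[r] - (region_sums[r] - p[i] + pi))
        return e

    trace = [mrf_energy(p, graph, regions, census, lam)]
    rng = rng_for(cfg.seed, "icm")
    for _sweep in range(cfg.max_sweeps):
        moved = 0
        for i in rng.permutation(n):
            pi = p[i]
            if pi == 0.0:
                continue
            e0 = local_energy(i, pi)
            best_e, best_p = e0, pi
            for cand in (pi * up, pi * down):
                e = local_energy(i, cand)
                if e < best_e:
                    best_e, best_p = e, cand
            if best_p != pi:
                r = region_of[i]
                if r >= 0:
                    region_sums[r] += best_p - pi
                p[i] = best_p
                moved += 1
        trace.append(mrf_energy(p, graph, regions, census, lam))
        if moved == 0:
            break
    out = np.zeros(init.grid.n_cells)
    out[graph.cell_index] = p
    return PopulationMap(init.grid, out.reshape(init.grid.shape), adjusted=True), trace
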