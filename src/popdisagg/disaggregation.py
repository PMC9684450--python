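"""Dasymetric disaggregation and learning-free baselines.

Dasymetric adjustment rescales a raw per-cell map within each census
region so the region's cell sum equals the census count exactly::

    p_adj(l_i) = c_j * p(l_i) / sum_{k in A_j} p(l_k)

When a region's raw sum is zero the weights are undefined; the fallback
chain is building counts (if supplied), then a uniform split over the
region's in-study cells, each with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

from .grids import (
    BuildingCountMap,
    CensusTable,
    PopulationMap,
    RegionMap,
    ValidationError,
)

__all__ = ["building_disaggregate", "dasymetric_adjust", "average_occupancy_baseline"]


def _split_by_weights(
    weights_flat: np.ndarray,
    regions: RegionMap,
    census: CensusTable,
    fallback_flat: np.ndarray | None,
    what: str,
) -> np.ndarray:
    """Allocate each region's census count proportionally to weights."""
    ids = regions.ids.ravel()
    out = np.zeros_like(weights_flat, dtype=np.float64)
    for rid in regions.region_ids():
        rid = int(rid)
        if rid not in census.entries:
            raise KeyError(f"region {rid} on the map is missing from the census table")
        cells = np.flatnonzero(ids == rid)
        w = weights_flat[cells]
        total = w.sum()
        if total <= 0:
            if fallback_flat is not None and fallback_flat[cells].sum() > 0:
                warnings.warn(
                    f"region {rid}: zero {what} weights, falling back to building counts",
                    stacklevel=3,
                )
                w = fallback_flat[cells]
                total = w.sum()
            else:
                warnings.warn(
                    f"region {rid}: zero {what} weights, falling back to uniform split",
                    stacklevel=3,
                )
                w = np.ones(len(cells))
                total = float(len(cells))
        out[cells] = census.entries[rid] * w / total
    return out


def building_disaggregate(
    buildings: BuildingCountMap, regions: RegionMap, census: CensusTable
) -> PopulationMap:
    """Split each region's census count proportionally to building counts."""
    buildings.grid.require_compatible(regions.grid, "regions")
    vals = _split_by_weights(
        buildings.counts.ravel().astype(np.float64), regions, census, None, "building"
    )
    return PopulationMap(regions.grid, vals.reshape(regions.grid.shape), adjusted=True)


def dasymetric_adjust(
    raw: PopulationMap,
    regions: RegionMap,
    census: CensusTable,
    buildings: BuildingCountMap | None = None,
) -> PopulationMap:
    """Rescale a raw map region-wise to match census counts exactly.

    Idempotent: adjusting an already-adjusted map changes nothing (each
    region is a fixed point of the rescaling). Scale-invariant in the
    raw map and order-preserving within each region.
    """
    raw.grid.require_compatible(regions.grid, "regions")
    if (raw.values < 0).any():
        raise ValidationError("raw map has negative values")
    fallback = None
    if buildings is not None:
        buildings.grid.require_compatible(regions.grid, "regions")
        fallback = buildings.counts.ravel().astype(np.float64)
    vals = _split_by_weights(raw.values.ravel(), regions, census, fallback, "prediction")
    return PopulationMap(regions.grid, vals.reshape(regions.grid.shape), adjusted=True)


def average_occupancy_baseline(
    training_totals: list[tuple[float, float]], target_buildings: BuildingCountMap
) -> PopulationMap:
    """Mean of per-landscape occupancy rates times the target building map.

    ``training_totals`` holds one ``(census_total, building_total)``
    pair per training landscape; landscapes without buildings are
    skipped with a warning. Rates are averaged unweighted across
    landscapes (not pooled).
    """
    rates = []
    for census_total, building_total in training_totals:
        if building_total <= 0:
            warnings.warn("training landscape with zero buildings skipped", stacklevel=2)
            continue
        rates.append(census_total / building_total)
    if not rates:
        raise ValidationError("no training landscape with positive building total")
    rate = float(np.mean(rates))
    return PopulationMap(
        target_buildings.grid,
        rate * target_buildings.counts.astype(np.float64),
        adjusted=False,
    )
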