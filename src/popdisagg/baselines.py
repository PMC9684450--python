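"""Learning-based comparison methods.

Two baselines frame the occupancy model:

* :class:`RegionForestRegressor` — the WorldPop-style random forest.
  Training units are whole census regions (features = per-channel
  means over the region's cells, target = log(1 + density) with
  density = count per cell); at inference every pixel's own feature
  vector is pushed through the forest, which induces the well-known
  aggregation-domain shift between region-level training and
  pixel-level prediction.
* :class:`CnnCountRegressor` — the same aggregated-supervision trainer
  as the occupancy network, but with 3x3 kernels and a head that
  outputs population directly (softplus, no building factor).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor

from .grids import (
    BuildingCountMap,
    CensusTable,
    CovariateStack,
    PopulationMap,
    RegionMap,
    ValidationError,
)
from .pomelo import PomeloRegressor

__all__ = [
    "aggregate_region_features",
    "RegionForestRegressor",
    "CnnCountRegressor",
    "train_region_rf",
    "predict_region_rf",
    "train_cnn_baseline",
]


def aggregate_region_features(
    stack: CovariateStack, regions: RegionMap, census: CensusTable,
    buildings: BuildingCountMap | None = None,
) -> pd.DataFrame:
    """One row per census region: per-channel means, cell count, count, density.

    Nodata cells are excluded from the channel means. When a building
    map is given, its per-cell counts join the covariates as an
    ordinary feature column (``building_count``), as in WorldPop-style
    pipelines where building layers are part of the covariate set.
    Regions present in the census but absent from the map are dropped
    with a warning.
    """
    stack.grid.require_compatible(regions.grid, "regions")
    ids = regions.ids.ravel()
    valid = ~stack.nodata_mask.ravel()
    flatX = stack.values.reshape(-1, stack.n_channels)
    names = list(stack.channels)
    if buildings is not None:
        buildings.grid.require_compatible(stack.grid, "buildings")
        flatX = np.column_stack([flatX, buildings.counts.ravel().astype(np.float64)])
        names = names + ["building_count"]
    rows = []
    present = set(int(r) for r in regions.region_ids())
    for rid in sorted(census.entries):
        if rid not in present:
            warnings.warn(f"census region {rid} has no cells on the map; dropped", stacklevel=2)
            continue
        cells = np.flatnonzero(ids == rid)
        ok = cells[valid[cells]]
        means = flatX[ok].mean(axis=0) if len(ok) else np.zeros(flatX.shape[1])
        count = census.entries[rid]
        rows.append(
            {"region_id": rid, "n_cells": len(cells), "population": count,
             "density": count / len(cells),
             **{ch: means[i] for i, ch in enumerate(names)}}
        )
    return pd.DataFrame(rows)


class RegionForestRegressor(BaseEstimator):
    """Random forest on region-mean covariates, predicting log(1 + density).

    The log back-transform plus the region-mean-to-pixel domain shift
    compresses the dynamic range of per-pixel predictions, so with
    ``calibrate_total`` (default) the fitted model carries a scalar
    ``scale_`` that rescales predictions so the summed prediction over
    the *training* regions matches the training census total — a
    training-side calibration that uses no held-out information.

    Attributes (fitted): ``forest_``, ``feature_names_``, ``scale_``.
    """

    def __init__(self, n_estimators: int = 500, min_regions: int = 10,
                 calibrate_total: bool = True, seed: int = 0):
        self.n_estimators = n_estimators
        self.min_regions = min_regions
        self.calibrate_total = calibrate_total
        self.seed = seed

    def fit(self, stack: CovariateStack, regions: RegionMap, census: CensusTable,
            buildings: BuildingCountMap | None = None):
        table = aggregate_region_features(stack, regions, census, buildings=buildings)
        if len(table) < self.min_regions:
            raise ValidationError(
                f"only {len(table)} training regions; need >= {self.min_regions}"
            )
        y = np.log1p(table["density"].to_numpy())
        if np.allclose(y, y[0]):
            warnings.warn("all training densities identical; forest will predict a constant",
                          stacklevel=2)
        self.feature_names_ = list(stack.channels) + (
            ["building_count"] if buildings is not None else []
        )
        X = table[self.feature_names_].to_numpy()
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1
        ).fit(X, y)
        self.scale_ = 1.0
        if self.calibrate_total:
            raw = self.predict(stack, regions, buildings=buildings)
            mask = regions.in_study_mask
            pred_total = float(raw.values[mask].sum())
            census_total = sum(census.entries[int(r)] for r in regions.region_ids()
                               if int(r) in census.entries)
            if pred_total > 0:
                self.scale_ = census_total / pred_total
        return self

    def predict(self, stack: CovariateStack, regions: RegionMap | None = None,
                buildings: BuildingCountMap | None = None) -> PopulationMap:
        """Per-pixel densities from each pixel's own feature vector."""
        if not hasattr(self, "forest_"):
            raise ValidationError("estimator is not fitted")
        expect_b = self.feature_names_[-1:] == ["building_count"]
        if list(stack.channels) != self.feature_names_[: len(stack.channels)] or (
            expect_b and buildings is None
        ):
            raise ValidationError("stack/buildings do not match the training feature set")
        mask = np.ones(stack.grid.shape, bool) if regions is None else regions.in_study_mask
        mask = mask & ~stack.nodata_mask
        out = np.zeros(stack.grid.shape)
        if mask.any():
            X = stack.values[mask]
            if expect_b:
                X = np.column_stack([X, buildings.counts[mask].astype(np.float64)])
            pred = self.forest_.predict(X)
            out[mask] = np.maximum(np.expm1(pred), 0.0) * getattr(self, "scale_", 1.0)
        return PopulationMap(stack.grid, out, adjusted=False)


class CnnCountRegressor(PomeloRegressor):
    """3x3-kernel variant trained to output population counts directly."""

    def __init__(
        self,
        depth: int = 4,
        hidden_width: int = 128,
        kernel_size: int = 3,
        dropout_p: float = 0.4,
        dropout_placement: str = "last",
        augment: bool = True,
        learning_rate: float = 1e-4,
        weight_decay_grid: tuple = (0.0, 1e-5, 1e-4, 1e-3),
        max_epochs: int = 300,
        batch_units: int = 8,
        augmentation_pairs_per_epoch: int | None = None,
        log_eps: float = 1.0,
        seed: int = 0,
    ):
        super().__init__(
            depth=depth,
            hidden_width=hidden_width,
            kernel_size=kernel_size,
            dropout_p=dropout_p,
            dropout_placement=dropout_placement,
            head="count",
            loss="log_l1",
            augment=augment,
            learning_rate=learning_rate,
            weight_decay_grid=weight_decay_grid,
            max_epochs=max_epochs,
            batch_units=batch_units,
            augmentation_pairs_per_epoch=augmentation_pairs_per_epoch,
            log_eps=log_eps,
            seed=seed,
        )


def train_region_rf(stack, regions, census, buildings=None, n_estimators=500,
                    seed=0) -> RegionForestRegressor:
    return RegionForestRegressor(n_estimators=n_estimators, seed=seed).fit(
        stack, regions, census, buildings=buildings
    )


def predict_region_rf(model: RegionForestRegressor, stack, regions=None,
                      buildings=None) -> PopulationMap:
    return model.predict(stack, regions, buildings=buildings)


def train_cnn_baseline(stack, buildings, regions, census, val_ids=None, **kwargs) -> CnnCountRegressor:
    model = CnnCountRegressor(**kwargs)
    model.fit(stack, buildings, regions, census, val_ids=val_ids)
    return model
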