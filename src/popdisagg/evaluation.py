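"""Metrics, cross-validation protocols, and feature importance.

Region-level metrics (computed on aggregated predictions c_hat vs
census c):

    R2   = 1 - sum (c_j - c_hat_j)^2 / sum (c_j - c_bar)^2   [percent]
    MAE  = mean |c_j - c_hat_j|                              [persons]
    MAPE = 100 * mean |c_j - c_hat_j| / c_j                  [percent]

Regions with zero census count are excluded from MAPE only (and
counted). Three evaluation protocols share one fivefold split of the
*coarse* regions (three folds train, one validation, one test, rotated
five times so the pooled test set covers every region exactly once):

* **coarse supervision** — train on coarse censuses, dasymetric-adjust
  the test-fold raw maps with the test folds' coarse censuses, score
  against the withheld fine censuses;
* **fine supervision** — identical folds (fine regions inherit their
  coarse parent's fold), train on fine censuses, score the *raw* test
  aggregates so no test census leaks into the prediction;
* **transfer** — train on other landscapes with fine supervision
  (80/20 region split for validation), predict absolute numbers on the
  whole target landscape with no census constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import derive_seed, rng_for
from .disaggregation import average_occupancy_baseline, building_disaggregate, dasymetric_adjust
from .grids import (
    BuildingCountMap,
    CensusTable,
    CovariateStack,
    PopulationMap,
    RegionMap,
    ValidationError,
)
from .mrf import MRFConfig, build_knn_graph, icm_disaggregate
from .pomelo import PomeloRegressor, RegionAggregate, SupervisionDataset, aggregate_to_regions
from .baselines import CnnCountRegressor, RegionForestRegressor

__all__ = [
    "MetricsReport",
    "FoldAssignment",
    "ImportanceReport",
    "compute_metrics",
    "make_folds",
    "run_fine_supervision",
    "run_coarse_supervision",
    "run_transfer",
    "permutation_importance",
    "LEARNING_METHODS",
    "LEARNING_FREE_METHODS",
]

LEARNING_METHODS = ("pomelo", "cnn", "rf", "avg")
LEARNING_FREE_METHODS = ("buildings", "mrf")


@dataclass
class MetricsReport:
    r2: float  # percent
    mae: float  # persons
    mape: float  # percent
    n_regions: int
    excluded_zero_census: int

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "mae": self.mae,
            "mape": self.mape,
            "n_regions": self.n_regions,
            "excluded_zero_census": self.excluded_zero_census,
        }


def compute_metrics(pred, census: CensusTable, min_census: float = 0.0) -> MetricsReport:
    """R2 / MAE / MAPE over the regions present in ``pred``.

    ``min_census`` additionally drops regions below a count threshold
    from MAPE (default off); dropped regions are counted in
    ``excluded_zero_census``.
    """
    entries = pred.entries if isinstance(pred, RegionAggregate) else dict(pred)
    ids = sorted(entries)
    if len(ids) < 2:
        raise ValidationError("R2 needs at least 2 regions")
    chat = np.array([entries[i] for i in ids], dtype=np.float64)
    c = census.counts_for(ids)
    ss_res = float(((c - chat) ** 2).sum())
    ss_tot = float(((c - c.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValidationError("R2 undefined: census counts are constant")
    r2 = 100.0 * (1.0 - ss_res / ss_tot)
    mae = float(np.abs(c - chat).mean())
    keep = c > max(0.0, min_census)
    excluded = int((~keep).sum())
    mape = float(100.0 * np.mean(np.abs(c[keep] - chat[keep]) / c[keep])) if keep.any() else 0.0
    return MetricsReport(r2=r2, mae=mae, mape=mape, n_regions=len(ids), excluded_zero_census=excluded)


@dataclass
class FoldAssignment:
    """Coarse-region id -> fold index; folds partition, sizes differ by <= 1."""

    assignment: dict[int, int]
    n_folds: int
    seed: int

    def fold_ids(self, fold: int) -> list[int]:
        return sorted(r for r, f in self.assignment.items() if f == fold)


def make_folds(coarse_ids, n_folds: int = 5, seed: int = 0) -> FoldAssignment:
    ids = [int(i) for i in coarse_ids]
    if len(ids) < n_folds:
        raise ValidationError(f"{len(ids)} regions cannot fill {n_folds} folds")
    rng = rng_for(seed, "folds")
    order = rng.permutation(len(ids))
    assignment = {ids[j]: int(i % n_folds) for i, j in enumerate(order)}
    return FoldAssignment(assignment=assignment, n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# method dispatch helpers


def _mask_regions(regions: RegionMap, keep_ids) -> RegionMap:
    keep = set(int(i) for i in keep_ids)
    ids = regions.ids.copy()
    ids[~np.isin(regions.ids, list(keep))] = 0
    return RegionMap(regions.grid, ids)


def _default_mrf_config(stack: CovariateStack, params: dict) -> MRFConfig:
    p = dict(params)
    if "feature_channels" not in p:
        named = [c for c in ("mean_building_area", "nightlight") if c in stack.channels]
        extra = named or list(stack.channels[:2])
        p["feature_channels"] = tuple(["building_count"] + extra)
    return MRFConfig(**p)


def _fit_learning_method(method, datasets, train_regions, val_regions, seed, params):
    """Fit pomelo/cnn/rf/avg on (dataset, region-id) unit lists."""
    params = dict(params or {})
    if method == "pomelo":
        model = PomeloRegressor(seed=seed, **params)
        return model.fit_multi(datasets, train_regions, val_regions)
    if method == "cnn":
        model = CnnCountRegressor(seed=seed, **params)
        return model.fit_multi(datasets, train_regions, val_regions)
    if method == "rf":
        # one pooled feature table over all training regions
        tables = []
        for d, ds in enumerate(datasets):
            rids = [r for dd, r in train_regions if dd == d]
            if not rids:
                continue
            sub_map = _mask_regions(ds.regions, rids)
            tables.append((ds.stack, sub_map, ds.census.subset(rids), ds.buildings))
        model = RegionForestRegressor(seed=seed, **params)
        return _fit_rf_pooled(model, tables)
    if method == "avg":
        totals = []
        for d, ds in enumerate(datasets):
            rids = [r for dd, r in train_regions if dd == d]
            if not rids:
                continue
            census_total = sum(ds.census.entries[r] for r in rids)
            cells_mask = np.isin(ds.regions.ids, rids)
            building_total = float(ds.buildings.counts[cells_mask].sum())
            totals.append((census_total, building_total))
        return ("avg", totals)
    raise ValidationError(f"unknown learning method {method!r}")


def _fit_rf_pooled(model: RegionForestRegressor, tables):
    from .baselines import aggregate_region_features
    import pandas as pd

    frames = [
        aggregate_region_features(stack, regions, census, buildings=b)
        for stack, regions, census, b in tables
    ]
    table = pd.concat(frames, ignore_index=True)
    if len(table) < model.min_regions:
        raise ValidationError(f"only {len(table)} training regions; need >= {model.min_regions}")
    stack0 = tables[0][0]
    y = np.log1p(table["density"].to_numpy())
    from sklearn.ensemble import RandomForestRegressor as _RF

    model.feature_names_ = list(stack0.channels) + ["building_count"]
    model.forest_ = _RF(
        n_estimators=model.n_estimators, random_state=model.seed, n_jobs=1
    ).fit(table[model.feature_names_].to_numpy(), y)
    model.scale_ = 1.0
    if model.calibrate_total:
        pred_total, census_total = 0.0, 0.0
        for stack, regions, census, b in tables:
            raw = model.predict(stack, regions, buildings=b)
            pred_total += float(raw.values[regions.in_study_mask].sum())
            census_total += sum(census.entries.values())
        if pred_total > 0:
            model.scale_ = census_total / pred_total
    return model


def _predict_raw(model, stack, buildings, regions) -> PopulationMap:
    if isinstance(model, tuple) and model[0] == "avg":
        return average_occupancy_baseline(model[1], buildings)
    if isinstance(model, RegionForestRegressor):
        return model.predict(stack, regions, buildings=buildings)
    return model.predict(stack, buildings, regions=regions)


# ---------------------------------------------------------------------------
# protocols


def _fold_metrics(agg, census):
    """Per-fold report; None when the fold has too few regions for R2."""
    try:
        return compute_metrics(agg, census)
    except ValidationError:
        warnings.warn("fold with fewer than 2 scored regions: per-fold metrics skipped",
                      stacklevel=2)
        return None


def _fold_sets(folds: FoldAssignment, rotation: int):
    """test = fold r, validation = fold r+1 (mod n), train = the rest."""
    test = folds.fold_ids(rotation)
    val = folds.fold_ids((rotation + 1) % folds.n_folds)
    train = [
        r
        for f in range(folds.n_folds)
        if f not in (rotation, (rotation + 1) % folds.n_folds)
        for r in folds.fold_ids(f)
    ]
    return train, val, test


def _fine_ids_of(data, coarse_ids) -> list[int]:
    keep = set(int(c) for c in coarse_ids)
    return sorted(
        f for f, c in data.hierarchy.fine_to_coarse.items()
        if c in keep and f in data.census_fine.entries
    )


def run_fine_supervision(data, method: str, folds: FoldAssignment, seed: int = 0,
                         method_params: dict | None = None) -> dict:
    """Fivefold protocol with fine-level supervision; scores raw test aggregates."""
    if method in LEARNING_FREE_METHODS:
        raise ValidationError(
            f"{method} only disaggregates known totals; it has no fine-supervision mode"
        )
    pooled: dict[int, float] = {}
    per_fold = []
    for r in range(folds.n_folds):
        train_c, val_c, test_c = _fold_sets(folds, r)
        train_f, val_f, test_f = (_fine_ids_of(data, s) for s in (train_c, val_c, test_c))
        ds = SupervisionDataset(data.covariates, data.buildings, data.regions, data.census_fine)
        model = _fit_learning_method(
            method, [ds], [(0, f) for f in train_f], [(0, f) for f in val_f],
            derive_seed(seed, method, "fine", r), method_params,
        )
        raw = _predict_raw(model, data.covariates, data.buildings, data.regions)
        agg = aggregate_to_regions(raw, _mask_regions(data.regions, test_f))
        for f in test_f:
            pooled[f] = agg.entries.get(f, 0.0)
        per_fold.append(_fold_metrics(agg, data.census_fine))
    return {
        "pooled": compute_metrics(pooled, data.census_fine),
        "per_fold": per_fold,
        "predictions": pooled,
    }


def run_coarse_supervision(data, method: str, folds: FoldAssignment, seed: int = 0,
                           method_params: dict | None = None) -> dict:
    """Fivefold protocol training on coarse censuses, scoring at the fine level.

    Learning methods predict raw maps without the test regions' census
    counts, which are then used only for dasymetric adjustment;
    learning-free methods disaggregate the test coarse censuses
    directly.
    """
    coarse_map = data.hierarchy.coarsen_map(data.regions)
    pooled: dict[int, float] = {}
    per_fold = []
    for r in range(folds.n_folds):
        train_c, val_c, test_c = _fold_sets(folds, r)
        test_f = _fine_ids_of(data, test_c)
        test_coarse_map = _mask_regions(coarse_map, test_c)
        test_coarse_census = data.census_coarse.subset(test_c)
        if method in LEARNING_FREE_METHODS:
            if method == "buildings":
                adj = building_disaggregate(data.buildings, test_coarse_map, test_coarse_census)
            else:
                init = building_disaggregate(data.buildings, test_coarse_map, test_coarse_census)
                cfg = _default_mrf_config(data.covariates, dict(method_params or {},
                                          seed=derive_seed(seed, "mrf", r)))
                graph = build_knn_graph(data.covariates, data.buildings, cfg)
                adj, _trace = icm_disaggregate(init, graph, test_coarse_map,
                                               test_coarse_census, cfg)
        else:
            ds = SupervisionDataset(data.covariates, data.buildings, coarse_map,
                                    data.census_coarse)
            model = _fit_learning_method(
                method, [ds], [(0, c) for c in train_c], [(0, c) for c in val_c],
                derive_seed(seed, method, "coarse", r), method_params,
            )
            raw = _predict_raw(model, data.covariates, data.buildings, coarse_map)
            adj = dasymetric_adjust(raw, test_coarse_map, test_coarse_census,
                                    buildings=data.buildings)
        agg = aggregate_to_regions(adj, _mask_regions(data.regions, test_f))
        for f in test_f:
            pooled[f] = agg.entries.get(f, 0.0)
        per_fold.append(_fold_metrics(agg, data.census_fine))
    return {
        "pooled": compute_metrics(pooled, data.census_fine),
        "per_fold": per_fold,
        "predictions": pooled,
    }


def run_transfer(landscapes, target_index: int, method: str, seed: int = 0,
                 n_runs: int = 5, method_params: dict | None = None) -> dict:
    """Train on the other landscapes, deploy on the target with no adjustment.

    Repeats ``n_runs`` seeded runs (fresh parameter init and 80/20
    train/validation region split each time) and reports mean and sd.
    """
    if len(landscapes) < 2:
        raise ValidationError("transfer needs at least 2 landscapes")
    if not 0 <= target_index < len(landscapes):
        raise ValidationError("target_index out of range")
    if method in LEARNING_FREE_METHODS:
        raise ValidationError(f"{method} cannot predict unconstrained absolute numbers")
    target = landscapes[target_index]
    train_landscapes = [d for i, d in enumerate(landscapes) if i != target_index]
    datasets = [
        SupervisionDataset(d.covariates, d.buildings, d.regions, d.census_fine)
        for d in train_landscapes
    ]
    pool = [
        (d, int(rid))
        for d, ds in enumerate(datasets)
        for rid in sorted(ds.census.entries)
        if rid in set(ds.regions.region_ids().tolist())
    ]
    runs = []
    for k in range(n_runs):
        run_seed = derive_seed(seed, "transfer", k)
        if method == "avg":
            model = _fit_learning_method(method, datasets, pool, [], run_seed, method_params)
        else:
            rng = rng_for(run_seed, "split")
            order = rng.permutation(len(pool))
            n_val = max(1, int(round(0.2 * len(pool))))
            val = [pool[i] for i in order[:n_val]]
            train = [pool[i] for i in order[n_val:]]
            model = _fit_learning_method(method, datasets, train, val, run_seed, method_params)
        raw = _predict_raw(model, target.covariates, target.buildings, target.regions)
        agg = aggregate_to_regions(raw, target.regions)
        scored = {f: agg.entries.get(f, 0.0) for f in sorted(target.census_fine.entries)}
        runs.append(compute_metrics(scored, target.census_fine))
    return {
        "runs": runs,
        "mean": {m: float(np.mean([getattr(r, m) for r in runs])) for m in ("r2", "mae", "mape")},
        "sd": {m: float(np.std([getattr(r, m) for r in runs])) for m in ("r2", "mae", "mape")},
    }


# ---------------------------------------------------------------------------
# permutation feature importance


@dataclass
class ImportanceReport:
    channels: list[str]
    drops: dict[str, dict[str, float]]  # channel -> {"r2": ..., "mae": ..., "mape": ...}
    baseline: MetricsReport
    n_repeats: int
    seed: int

    def ranked_by_r2_drop(self) -> list[str]:
        return sorted(self.channels, key=lambda c: -self.drops[c]["r2"])


def permutation_importance(model, stack: CovariateStack, buildings: BuildingCountMap,
                           regions: RegionMap, census: CensusTable,
                           n_repeats: int = 3, seed: int = 0) -> ImportanceReport:
    """Metric drop after shuffling one covariate across the active cells.

    The channel's values are permuted among cells with at least one
    building (the cells the model actually reads), predictions are
    recomputed, and the drop in each metric relative to the unshuffled
    baseline is averaged over ``n_repeats`` seeded repetitions.
    Positive drops mean the channel mattered.
    """
    eval_ids = [int(r) for r in regions.region_ids() if int(r) in census.entries]
    eval_map = _mask_regions(regions, eval_ids)

    def _score(stk) -> MetricsReport:
        raw = _predict_raw(model, stk, buildings, regions)
        return compute_metrics(aggregate_to_regions(raw, eval_map), census)

    base = _score(stack)
    active = np.flatnonzero(buildings.active_mask.ravel())
    drops: dict[str, dict[str, float]] = {}
    for ci, name in enumerate(stack.channels):
        acc = {"r2": 0.0, "mae": 0.0, "mape": 0.0}
        for rep in range(n_repeats):
            rng = rng_for(seed, "perm", name, rep)
            values = stack.values.copy()
            flat = values.reshape(-1, stack.n_channels)
            flat[active, ci] = flat[active[rng.permutation(len(active))], ci]
            perm_stack = CovariateStack(stack.grid, list(stack.channels), values,
                                        nodata_mask=stack.nodata_mask)
            m = _score(perm_stack)
            acc["r2"] += base.r2 - m.r2
            acc["mae"] += m.mae - base.mae
            acc["mape"] += m.mape - base.mape
        drops[name] = {k: v / n_repeats for k, v in acc.items()}
    return ImportanceReport(
        channels=list(stack.channels), drops=drops, baseline=base,
        n_repeats=n_repeats, seed=seed,
    )
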