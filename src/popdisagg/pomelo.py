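"""Occupancy-rate regression from aggregated census supervision.

The model predicts a per-cell building *occupancy rate* (people per
building) from the covariates with a small per-pixel network, and turns
it into population by multiplying with the building count::

    p_hat(l_i) = f_theta(X(l_i)) * b(l_i)

Because per-cell ground truth does not exist, training compares
*aggregated* predictions per administrative region with the region's
census count (weak supervision):

    argmin_theta  sum_j  L( sum_{i in A_j} p_hat(l_i),  c_j )

with the L1 distance between log-transformed counts as loss. Counts are
floored at ``log_eps`` (default one person) inside the logs so empty or
near-empty regions stay finite. Data augmentation merges random pairs
of regions into "pseudo-regions" (union of cells, sum of counts),
re-drawn every epoch.

:class:`PomeloRegressor` is a scikit-learn-style estimator
(``get_params``/``set_params``, fitted attributes with trailing
underscore). ``head='count'`` with ``loss='l1'`` and no augmentation
gives the direct-regression ablation baseline; ``kernel_size=3`` with
``head='count'`` gives the CNN comparison model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from ._utils import derive_seed, rng_for, softplus
from .grids import (
    BuildingCountMap,
    CensusTable,
    CovariateStack,
    GridSpec,
    PopulationMap,
    RegionMap,
    ValidationError,
)
from .nn import Adam, ConvNet, NetworkSpec, count_params

__all__ = [
    "OccupancyMap",
    "RegionAggregate",
    "TrainingConfig",
    "TrainingUnit",
    "SupervisionDataset",
    "PomeloRegressor",
    "init_network",
    "predict_occupancy",
    "predict_population",
    "aggregate_to_regions",
    "log_l1_loss",
    "merge_pseudo_regions",
    "train_pomelo",
]


@dataclass
class OccupancyMap:
    """Per-cell occupancy rates; defined (positive) on active cells, 0 elsewhere."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValidationError("occupancy shape mismatch")
        if (self.values < 0).any():
            raise ValidationError("negative occupancy")


@dataclass
class RegionAggregate:
    """Predicted count per region id."""

    entries: dict[int, float]

    def counts_for(self, ids) -> np.ndarray:
        return np.array([self.entries[int(i)] for i in ids], dtype=np.float64)


@dataclass
class TrainingConfig:
    """Optimization hyper-parameters for aggregated-supervision training."""

    learning_rate: float = 1e-4
    optimizer: str = "Adam"
    weight_decay_grid: tuple = (0.0, 1e-5, 1e-4, 1e-3)
    max_epochs: int = 300
    checkpoint_metric: str = "validation MAPE"
    augmentation_pairs_per_epoch: int | None = None  # None -> n_regions // 2
    log_eps: float = 1.0
    batch_units: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.log_eps <= 0:
            raise ValidationError("log_eps must be > 0")


@dataclass(frozen=True)
class TrainingUnit:
    """One supervision unit: a cell set with a target count.

    ``region_ids`` holds one id for a real region, two for a
    pseudo-region created by merging.
    """

    dataset: int
    region_ids: tuple
    cells: np.ndarray
    target: float


def init_network(spec: NetworkSpec, seed: int = 0) -> ConvNet:
    """Fan-in-scaled random initialization, deterministic given seed."""
    net = ConvNet(spec, seed=seed)
    assert net.n_params == count_params(spec)
    return net


def predict_population(occupancy: OccupancyMap, buildings: BuildingCountMap) -> PopulationMap:
    """p_hat = occupancy * building count; exactly zero wherever b = 0."""
    occupancy.grid.require_compatible(buildings.grid, "buildings")
    if (occupancy.values < 0).any():
        raise ValidationError("negative occupancy input")
    values = occupancy.values * buildings.counts
    return PopulationMap(occupancy.grid, values, adjusted=False)


def aggregate_to_regions(pop: PopulationMap, regions: RegionMap) -> RegionAggregate:
    """Sum predicted population per region id present on the map."""
    pop.grid.require_compatible(regions.grid, "regions")
    ids = regions.ids.ravel()
    sums = np.bincount(ids, weights=pop.values.ravel())
    present = regions.region_ids()
    return RegionAggregate({int(r): float(sums[r]) for r in present})


def _as_entries(x) -> dict[int, float]:
    if isinstance(x, RegionAggregate):
        return x.entries
    if isinstance(x, CensusTable):
        return x.entries
    return dict(x)


def log_l1_loss(pred, census, log_eps: float = 1.0) -> float:
    """Sum over regions of |log(max(chat, eps)) - log(max(c, eps))|."""
    p = _as_entries(pred)
    c = _as_entries(census)
    total = 0.0
    for rid, phat in p.items():
        if rid not in c:
            raise KeyError(f"region {rid} missing from census")
        total += abs(np.log(max(phat, log_eps)) - np.log(max(c[rid], log_eps)))
    return float(total)


def _draw_pairs(region_ids: list, n_pairs: int, rng: np.random.Generator) -> list[tuple]:
    """Random disjoint pairs; several permutation rounds if n_pairs > n//2."""
    pairs: list[tuple] = []
    n = len(region_ids)
    while len(pairs) < n_pairs:
        order = rng.permutation(n)
        for a, b in zip(order[0::2], order[1::2]):
            pairs.append((region_ids[a], region_ids[b]))
            if len(pairs) == n_pairs:
                break
    return pairs


def merge_pseudo_regions(
    regions: RegionMap, census: CensusTable, n_pairs: int, seed: int = 0
) -> list[TrainingUnit]:
    """Original region units plus ``n_pairs`` merged pseudo-region units."""
    if n_pairs < 0:
        raise ValidationError("n_pairs must be >= 0")
    ids = [int(r) for r in regions.region_ids() if int(r) in census.entries]
    if len(ids) < 2 and n_pairs > 0:
        raise ValidationError("need at least 2 regions to build pseudo-regions")
    flat = regions.ids.ravel()
    cells = {r: np.flatnonzero(flat == r) for r in ids}
    units = [TrainingUnit(0, (r,), cells[r], census.entries[r]) for r in ids]
    rng = rng_for(seed, "pseudo-regions")
    for a, b in _draw_pairs(ids, n_pairs, rng):
        units.append(
            TrainingUnit(
                0,
                (a, b),
                np.concatenate([cells[a], cells[b]]),
                census.entries[a] + census.entries[b],
            )
        )
    return units


@dataclass
class SupervisionDataset:
    """One landscape's rasters and the census used for supervision."""

    stack: CovariateStack
    buildings: BuildingCountMap
    regions: RegionMap
    census: CensusTable

    def __post_init__(self) -> None:
        g = self.stack.grid
        g.require_compatible(self.buildings.grid, "buildings")
        g.require_compatible(self.regions.grid, "regions")


class _PreparedLandscape:
    """Cell tables (kernel 1) or grids (kernel > 1) for one dataset."""

    def __init__(self, ds: SupervisionDataset, head: str, kernel_size: int):
        grid = ds.stack.grid
        b_flat = ds.buildings.counts.ravel().astype(np.float64)
        in_study = (ds.regions.ids.ravel() > 0).astype(np.float64)
        nodata = ds.stack.nodata_mask.ravel()
        if head == "occupancy":
            wt_flat = b_flat
        else:
            wt_flat = in_study.copy()
        wt_flat = np.where(nodata, 0.0, wt_flat)
        self.grid = grid
        self.kernel_size = kernel_size
        if kernel_size == 1:
            # restrict to cells that can contribute to any aggregate
            self.cell_index = np.flatnonzero(wt_flat > 0)
            self.pos_of = np.full(grid.n_cells, -1, dtype=np.int64)
            self.pos_of[self.cell_index] = np.arange(len(self.cell_index))
            flatX = ds.stack.values.reshape(-1, ds.stack.n_channels)
            self.X = flatX[self.cell_index]
            self.wt = wt_flat[self.cell_index]
        else:
            self.Xgrid = ds.stack.values
            self.wt = wt_flat

    def unit_positions(self, cells: np.ndarray) -> np.ndarray:
        """Map flat grid indices to rows of the prepared table (k=1 path)."""
        pos = self.pos_of[cells]
        return pos[pos >= 0]


class PomeloRegressor(BaseEstimator):
    """Per-pixel occupancy network trained on aggregated census counts.

    Parameters
    ----------
    head : {'occupancy', 'count'}
        'occupancy' multiplies the softplus output by the building
        count (the factorized model); 'count' outputs population
        directly (the ablation / CNN-style head).
    loss : {'log_l1', 'l1'}
        Region-level loss on aggregated counts.
    augment : bool
        Re-draw pseudo-region pairs each epoch and append them to the
        training units.
    weight_decay_grid : sequence of float
        L2 strengths tried; the snapshot with the best validation MAPE
        across the whole grid is kept.

    Attributes
    ----------
    net_ : ConvNet               fitted network (best checkpoint)
    norm_mean_, norm_std_ :      per-channel z-scoring statistics,
                                 computed on training cells only
    best_weight_decay_ : float   grid winner
    best_val_mape_ : float
    history_ : dict              per-weight-decay epoch traces
    n_params_ : int
    """

    def __init__(
        self,
        depth: int = 4,
        hidden_width: int = 128,
        kernel_size: int = 1,
        dropout_p: float = 0.4,
        dropout_placement: str = "last",
        head: str = "occupancy",
        loss: str = "log_l1",
        augment: bool = True,
        learning_rate: float = 1e-4,
        weight_decay_grid: tuple = (0.0, 1e-5, 1e-4, 1e-3),
        max_epochs: int = 300,
        batch_units: int = 8,
        augmentation_pairs_per_epoch: int | None = None,
        log_eps: float = 1.0,
        seed: int = 0,
    ):
        self.depth = depth
        self.hidden_width = hidden_width
        self.kernel_size = kernel_size
        self.dropout_p = dropout_p
        self.dropout_placement = dropout_placement
        self.head = head
        self.loss = loss
        self.augment = augment
        self.learning_rate = learning_rate
        self.weight_decay_grid = weight_decay_grid
        self.max_epochs = max_epochs
        self.batch_units = batch_units
        self.augmentation_pairs_per_epoch = augmentation_pairs_per_epoch
        self.log_eps = log_eps
        self.seed = seed

    # ------------------------------------------------------------------
    def fit(self, stack, buildings, regions, census, val_ids=None, val_fraction=0.2):
        """Single-landscape convenience around :meth:`fit_multi`.

        ``val_ids`` lists the region ids held out for validation MAPE;
        if omitted a seeded ``val_fraction`` of the regions is held out.
        """
        ds = SupervisionDataset(stack, buildings, regions, census)
        ids = [int(r) for r in regions.region_ids() if int(r) in census.entries]
        if val_ids is None:
            rng = rng_for(self.seed, "valsplit")
            n_val = max(1, int(round(val_fraction * len(ids))))
            val_ids = [ids[i] for i in rng.permutation(len(ids))[:n_val]]
        val_ids = [int(v) for v in val_ids]
        train_ids = [r for r in ids if r not in set(val_ids)]
        return self.fit_multi(
            [ds], [(0, r) for r in train_ids], [(0, r) for r in val_ids]
        )

    def fit_multi(self, datasets, train_regions, val_regions):
        """Fit on (dataset index, region id) unit lists, possibly spanning landscapes."""
        if set(train_regions) & set(val_regions):
            raise ValidationError("validation regions overlap training regions")
        if not train_regions:
            raise ValidationError("no training regions")
        n_channels = datasets[0].stack.n_channels
        for ds in datasets:
            if ds.stack.n_channels != n_channels:
                raise ValidationError("datasets disagree on channel count")
        spec = NetworkSpec(
            n_inputs=n_channels,
            depth=self.depth,
            hidden_width=self.hidden_width,
            kernel_size=self.kernel_size,
            dropout_p=self.dropout_p,
            dropout_placement=self.dropout_placement,
        )
        prepared = [_PreparedLandscape(ds, self.head, self.kernel_size) for ds in datasets]

        units = self._build_units(datasets, prepared, train_regions)
        val_units = self._build_units(datasets, prepared, val_regions)
        contributing = 0
        for u in units:
            land = prepared[u.dataset]
            if land.kernel_size == 1:
                contributing += len(land.unit_positions(u.cells))
            else:
                contributing += int((land.wt[u.cells] > 0).sum())
        if contributing == 0:
            raise ValidationError("degenerate input: no contributing cells in training regions")

        self._fit_normalization(prepared, units)

        best = None
        history: dict[float, dict] = {}
        for wd in self.weight_decay_grid:
            net, trace = self._optimize(spec, prepared, units, val_units, wd)
            history[wd] = trace
            if best is None or trace["best_val_mape"] < best[0]:
                best = (trace["best_val_mape"], wd, net)
        self.best_val_mape_, self.best_weight_decay_, self.net_ = best
        self.spec_ = spec
        self.history_ = history
        self.n_params_ = self.net_.n_params
        return self

    # ------------------------------------------------------------------
    def _build_units(self, datasets, prepared, region_list):
        units = []
        for d, rid in region_list:
            flat = datasets[d].regions.ids.ravel()
            cells = np.flatnonzero(flat == int(rid))
            try:
                target = datasets[d].census.entries[int(rid)]
            except KeyError:
                raise KeyError(f"region {rid} missing from census of dataset {d}") from None
            units.append(TrainingUnit(d, (int(rid),), cells, target))
        return units

    def _fit_normalization(self, prepared, units):
        """Per-channel z-stats over the training units' contributing cells."""
        rows = []
        for d, land in enumerate(prepared):
            cells = np.unique(
                np.concatenate([u.cells for u in units if u.dataset == d] or [np.array([], int)])
            ).astype(np.int64)
            if land.kernel_size == 1:
                pos = land.unit_positions(cells)
                if len(pos):
                    rows.append(land.X[pos])
            else:
                flatX = land.Xgrid.reshape(-1, land.Xgrid.shape[2])
                mask = land.wt[cells] > 0
                if mask.any():
                    rows.append(flatX[cells[mask]])
        allrows = np.vstack(rows)
        self.norm_mean_ = allrows.mean(axis=0)
        self.norm_std_ = np.maximum(allrows.std(axis=0), 1e-6)
        for land in prepared:
            if land.kernel_size == 1:
                land.Xn = (land.X - self.norm_mean_) / self.norm_std_
            else:
                land.Xn = (land.Xgrid - self.norm_mean_) / self.norm_std_

    # ------------------------------------------------------------------
    def _unit_aggregate_eval(self, net, prepared, units) -> np.ndarray:
        """Eval-mode aggregated prediction per unit (no dropout)."""
        chat = np.zeros(len(units))
        by_ds: dict[int, list[int]] = {}
        for i, u in enumerate(units):
            by_ds.setdefault(u.dataset, []).append(i)
        for d, idxs in by_ds.items():
            land = prepared[d]
            if land.kernel_size == 1:
                cat = np.concatenate([land.unit_positions(units[i].cells) for i in idxs])
                seg = np.repeat(
                    np.arange(len(idxs)),
                    [len(land.unit_positions(units[i].cells)) for i in idxs],
                )
                if len(cat) == 0:
                    continue
                uniq, inv = np.unique(cat, return_inverse=True)
                z, _ = net.forward_cells(land.Xn[uniq])
                p = softplus(z) * land.wt[uniq]
                sums = np.bincount(seg, weights=p[inv], minlength=len(idxs))
            else:
                z, _ = net.forward_grid(land.Xn)
                p = softplus(z) * land.wt
                sums = np.array([p[units[i].cells].sum() for i in idxs])
            for j, i in enumerate(idxs):
                chat[i] = sums[j]
        return chat

    def _loss_and_grad_wrt_chat(self, chat: np.ndarray, targets: np.ndarray):
        eps = self.log_eps
        if self.loss == "log_l1":
            lp = np.log(np.maximum(chat, eps))
            lc = np.log(np.maximum(targets, eps))
            loss = float(np.abs(lp - lc).sum())
            grad = np.where(chat > eps, np.sign(lp - lc) / np.maximum(chat, eps), 0.0)
        elif self.loss == "l1":
            loss = float(np.abs(chat - targets).sum())
            grad = np.sign(chat - targets)
        else:
            raise ValidationError(f"unknown loss {self.loss!r}")
        return loss, grad

    def _batch_step(self, net, opt, prepared, batch, drop_rng):
        grads_total = None
        loss_total = 0.0
        by_ds: dict[int, list[TrainingUnit]] = {}
        for u in batch:
            by_ds.setdefault(u.dataset, []).append(u)
        for d, us in by_ds.items():
            land = prepared[d]
            targets = np.array([u.target for u in us])
            if land.kernel_size == 1:
                pos_lists = [land.unit_positions(u.cells) for u in us]
                cat = np.concatenate(pos_lists) if pos_lists else np.array([], int)
                if len(cat) == 0:
                    chat = np.zeros(len(us))
                    loss, _ = self._loss_and_grad_wrt_chat(chat, targets)
                    loss_total += loss
                    continue
                seg = np.repeat(np.arange(len(us)), [len(p) for p in pos_lists])
                uniq, inv = np.unique(cat, return_inverse=True)
                z, cache = net.forward_cells(land.Xn[uniq], dropout_rng=drop_rng)
                act = softplus(z)
                p = act * land.wt[uniq]
                chat = np.bincount(seg, weights=p[inv], minlength=len(us))
                loss, dchat = self._loss_and_grad_wrt_chat(chat, targets)
                loss_total += loss
                dp = np.bincount(inv, weights=dchat[seg], minlength=len(uniq))
                dz = dp * land.wt[uniq] * expit(z)
                grads = net.backward_cells(cache, dz)
            else:
                z, cache = net.forward_grid(land.Xn, dropout_rng=drop_rng)
                p = softplus(z) * land.wt
                chat = np.array([p[u.cells].sum() for u in us])
                loss, dchat = self._loss_and_grad_wrt_chat(chat, targets)
                loss_total += loss
                dp = np.zeros(len(p))
                for u, g in zip(us, dchat):
                    np.add.at(dp, u.cells, g)
                dz = dp * land.wt * expit(z)
                grads = net.backward_grid(cache, dz)
            if grads_total is None:
                grads_total = grads
            else:
                for gt, g in zip(grads_total, grads):
                    gt += g
        if grads_total is not None:
            opt.step(grads_total)
        return loss_total

    def _optimize(self, spec, prepared, units, val_units, weight_decay):
        net = init_network(spec, seed=derive_seed(self.seed, "init"))
        opt = Adam(net.get_flat_params(), lr=self.learning_rate, weight_decay=weight_decay)
        order_rng = rng_for(self.seed, "order", weight_decay)
        drop_rng = rng_for(self.seed, "dropout", weight_decay)
        n_pairs = self.augmentation_pairs_per_epoch
        if n_pairs is None:
            n_pairs = len(units) // 2
        val_targets = np.array([u.target for u in val_units])
        trace = {"train_loss": [], "val_mape": [], "best_val_mape": np.inf, "best_epoch": -1}
        best_params = net.copy_params()
        pools: dict[int, list[TrainingUnit]] = {}
        for u in units:
            pools.setdefault(u.dataset, []).append(u)
        n_units = len(units)
        for epoch in range(self.max_epochs):
            epoch_units = list(units)
            if self.augment and n_pairs > 0:
                pair_rng = rng_for(self.seed, "aug", weight_decay, epoch)
                # pairs are drawn within a landscape (cells of a pseudo-region
                # must live on one grid); each landscape gets a share of
                # n_pairs proportional to its region count
                for d, pool in sorted(pools.items()):
                    if len(pool) < 2:
                        continue
                    share = max(1, int(round(n_pairs * len(pool) / n_units)))
                    for ua, ub in _draw_pairs(pool, share, pair_rng):
                        epoch_units.append(
                            TrainingUnit(
                                d,
                                ua.region_ids + ub.region_ids,
                                np.concatenate([ua.cells, ub.cells]),
                                ua.target + ub.target,
                            )
                        )
            order = order_rng.permutation(len(epoch_units))
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_units):
                batch = [epoch_units[i] for i in order[start : start + self.batch_units]]
                epoch_loss += self._batch_step(net, opt, prepared, batch, drop_rng)
            if not np.isfinite(epoch_loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            trace["train_loss"].append(epoch_loss)
            if val_units:
                chat = self._unit_aggregate_eval(net, prepared, val_units)
                ok = val_targets > 0
                if ok.any():
                    mape = float(
                        100.0 * np.mean(np.abs(chat[ok] - val_targets[ok]) / val_targets[ok])
                    )
                else:
                    mape = float(np.abs(chat - val_targets).mean())
            else:
                mape = epoch_loss
            trace["val_mape"].append(mape)
            if mape < trace["best_val_mape"]:
                trace["best_val_mape"] = mape
                trace["best_epoch"] = epoch
                best_params = net.copy_params()
        net.set_params_from(best_params)
        return net, trace

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise ValidationError("estimator is not fitted")

    def predict_occupancy(self, stack: CovariateStack, buildings: BuildingCountMap) -> OccupancyMap:
        """Eval-mode occupancy rates on active cells; 0 elsewhere."""
        self._check_fitted()
        if self.head != "occupancy":
            raise ValidationError("predict_occupancy requires head='occupancy'")
        if stack.n_channels != self.spec_.n_inputs:
            raise ValidationError(
                f"stack has {stack.n_channels} channels, model expects {self.spec_.n_inputs}"
            )
        out = np.zeros(stack.grid.shape)
        active = buildings.active_mask & ~stack.nodata_mask
        if active.any():
            Xn = (stack.values[active] - self.norm_mean_) / self.norm_std_
            if self.kernel_size == 1:
                z, _ = self.net_.forward_cells(Xn)
                out[active] = softplus(z)
            else:
                Xg = (stack.values - self.norm_mean_) / self.norm_std_
                z, _ = self.net_.forward_grid(Xg)
                out[active] = softplus(z).reshape(stack.grid.shape)[active]
        return OccupancyMap(stack.grid, out)

    def predict(self, stack: CovariateStack, buildings: BuildingCountMap,
                regions: RegionMap | None = None) -> PopulationMap:
        """Raw (unadjusted) population map.

        With the occupancy head, population is occupancy times building
        count (zero off the active mask). With the count head the
        network output itself is the population, evaluated on in-study
        cells (``regions`` required to delimit them, else everywhere).
        """
        self._check_fitted()
        if stack.n_channels != self.spec_.n_inputs:
            raise ValidationError(
                f"stack has {stack.n_channels} channels, model expects {self.spec_.n_inputs}"
            )
        if self.head == "occupancy":
            return predict_population(self.predict_occupancy(stack, buildings), buildings)
        mask = np.ones(stack.grid.shape, dtype=bool) if regions is None else regions.in_study_mask
        mask = mask & ~stack.nodata_mask
        out = np.zeros(stack.grid.shape)
        if mask.any():
            if self.kernel_size == 1:
                Xn = (stack.values[mask] - self.norm_mean_) / self.norm_std_
                z, _ = self.net_.forward_cells(Xn)
                out[mask] = softplus(z)
            else:
                Xg = (stack.values - self.norm_mean_) / self.norm_std_
                z, _ = self.net_.forward_grid(Xg)
                out[mask] = softplus(z).reshape(stack.grid.shape)[mask]
        return PopulationMap(stack.grid, out, adjusted=False)


def train_pomelo(
    stack: CovariateStack,
    buildings: BuildingCountMap,
    regions: RegionMap,
    census: CensusTable,
    val_ids=None,
    config: TrainingConfig | None = None,
    spec: NetworkSpec | None = None,
) -> tuple[PomeloRegressor, dict]:
    """Functional wrapper: fit a :class:`PomeloRegressor`, return (model, history)."""
    cfg = config or TrainingConfig()
    kwargs = dict(
        learning_rate=cfg.learning_rate,
        weight_decay_grid=tuple(cfg.weight_decay_grid),
        max_epochs=cfg.max_epochs,
        batch_units=cfg.batch_units,
        augmentation_pairs_per_epoch=cfg.augmentation_pairs_per_epoch,
        log_eps=cfg.log_eps,
        seed=cfg.seed,
    )
    if spec is not None:
        kwargs.update(
            depth=spec.depth,
            hidden_width=spec.hidden_width,
            kernel_size=spec.kernel_size,
            dropout_p=spec.dropout_p,
            dropout_placement=spec.dropout_placement,
        )
    model = PomeloRegressor(**kwargs)
    model.fit(stack, buildings, regions, census, val_ids=val_ids)
    return model, model.history_


def predict_occupancy(model: PomeloRegressor, stack, buildings) -> OccupancyMap:
    """Module-level alias for :meth:`PomeloRegressor.predict_occupancy`."""
    return model.predict_occupancy(stack, buildings)
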