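# Methods

## Problem setting

Top-down population disaggregation: given (a) census counts for the
regions of an administrative level, (b) a building-count raster and
(c) a stack of co-registered covariate rasters at 100 m ground
sampling distance, produce a per-cell population map whose regional
aggregates are faithful — and, in the supervised settings, predictive
for *finer* regions than the supervision level. Supervision is weak:
the only labels are sums of the quantity of interest over large groups
of cells.

## The occupancy model

The estimator factorizes population into `occupancy x building count`.
The occupancy network is a per-pixel MLP expressed as 1×1
convolutions: `depth=4` layers, hidden width 128, ReLU activations,
dropout `p=0.4`, and a softplus on the scalar output so occupancy is
strictly positive. Covariates are z-scored per channel with statistics
computed on the *training* cells only and reused verbatim at
inference, which is what makes cross-landscape transfer meaningful.

Cells without buildings contribute exactly zero population for any
parameter value — the factorization guarantees the mask invariant
structurally, and with 1×1 kernels the whole computation is restricted
to the built-up cells (a few percent of the grid).

**Dropout placement.** One dropout layer sits after the last hidden
layer (`dropout_placement='last'`; `'all'` applies it after every
hidden layer). With aggregated supervision the number of training
units is the number of regions — tens, not thousands — and dropout at
every hidden layer at p=0.4 injects so much gradient noise and
train/eval output bias that the network never learns the covariate
signal: in our diagnostics the per-cell occupancy correlation with the
generating field stayed near 0.05 and eval-mode aggregates were biased
about −35% while the train-mode fit looked good. A single late dropout
layer regularizes the head without drowning the signal (occupancy
correlation 0.5–0.9 in the same setting). The rate itself stays 0.4.

**Loss.** Region-level L1 distance between log-transformed counts,
summed over supervision units. Counts are clamped at `log_eps = 1`
person inside the logarithms; an empty or zero-census region therefore
contributes a finite term and a zero gradient once the prediction is
below one person. Summing (rather than averaging) over units only
rescales the learning rate.

**Optimization.** Adam, base learning rate 1e-4, weight decay added to
the gradient (classic L2) and grid-searched over
`{0, 1e-5, 1e-4, 1e-3}` by default; each grid value trains from the
same seeded initialization, and the parameter snapshot with the best
validation MAPE across the whole grid is kept. An epoch processes all
supervision units once in a seeded shuffled order, in batches of 8
units; the per-epoch validation MAPE is computed in eval mode (no
dropout) on raw, unadjusted aggregates, so checkpointing never sees a
held-out census used for scoring. Default `max_epochs = 300`; with
best-MAPE checkpointing the exact count is not critical. Training
diverging to a non-finite loss raises with the epoch index.

**Pseudo-region augmentation.** Each epoch draws `n_units // 2`
disjoint random pairs of training regions (within a landscape) and
appends, per pair, one synthetic unit whose cell set is the union and
whose target is the sum. Pairings are redrawn every epoch from an
epoch-derived seed.

**Estimator surface.** `PomeloRegressor` follows the scikit-learn
estimator protocol (constructor hyper-parameters, `get_params` /
`set_params`, fitted attributes with trailing underscores:
`net_`, `norm_mean_`, `norm_std_`, `best_weight_decay_`,
`best_val_mape_`, `history_`). `head='count'` removes the building
factor (the network outputs population directly), `loss='l1'` switches
to plain L1, `augment=False` disables pseudo-regions — together these
give the ablation baseline; `CnnCountRegressor` is the 3×3-kernel,
direct-count configuration. The network itself (forward, backward,
Adam) is a self-contained numpy implementation; with 3×3 kernels the
forward pass runs on the full grid via im2col and the mask is applied
afterwards.

## Learning-free methods

`building_disaggregate` splits each region's census proportionally to
building counts. `dasymetric_adjust` rescales any non-negative raw map
so each region's sum equals its census exactly; it is idempotent,
scale-invariant and order-preserving within regions. Regions whose
weights sum to zero fall back to building counts, then to a uniform
split, each with a warning — the adjustment formula is undefined
there and the fallback chain is a package decision.

The MRF baseline minimizes
`sum_i sum_{k in Q_i} |p_i - p_k| + lambda * sum_j |c_j - sum_{A_j} p_k|`
over the active cells, where `Q_i` are the k nearest neighbours in a
z-normalized covariate feature space (`lambda = 1`). The double sum is
directed (each ordered pair once); the symmetrized reading only
rescales the smoothness weight. Minimization is ICM: seeded random
sweep order, per-cell candidate set `{p_i, 1.01 p_i, 0.99 p_i}`
(multiplicative ±1% steps), move accepted only when it strictly lowers
the energy, stop after a sweep with no accepted move or `max_sweeps =
100`. The energy trace is recomputed globally each sweep and is
non-increasing by construction. A cell at zero stays at zero —
multiplicative steps cannot leave it — hence the recommended
initialization by building-count disaggregation, which is positive on
every active cell of a populated region. `k_neighbors` defaults to 10.
The kNN graph is exact (full distance matrix, stable argsort, ties to
the lowest cell index) up to 4000 active cells and tree-based above.

The region-level random forest regresses `log(1 + density)` (density =
census count per cell) on per-region mean covariates, with the
building count included as an ordinary feature; 500 trees. At
inference each pixel's own feature vector goes through the forest —
deliberately reproducing the aggregation-domain shift of that method
family. Because the log back-transform plus that shift compress the
predicted dynamic range, the fitted model carries a scalar `scale_`
that rescales predictions so the training regions' summed prediction
matches the training census total; the calibration uses training-side
information only.

The naive transfer baseline multiplies the target's building map by
the unweighted mean of per-landscape occupancy rates
(census total / building total) of the training landscapes.

## Evaluation

Metrics at region level, on aggregated counts: R² in percent, MAE in
persons, MAPE in percent with zero-census regions excluded (and
counted); an optional `min_census` filter additionally drops regions
below a count threshold, default off. R² requires at least two
regions.

All protocols share one fivefold seeded partition of the *coarse*
regions (fold sizes within one). Rotation `r` tests fold `r`,
validates on fold `r+1 (mod 5)` and trains on the rest, so the pooled
test set covers every region exactly once:

* **Coarse supervision** — train on coarse censuses; predict raw maps
  on test folds; dasymetrically adjust with the test folds' *coarse*
  censuses; aggregate to fine regions and score against the withheld
  fine censuses. Learning-free methods disaggregate the test coarse
  censuses directly.
* **Fine supervision** — identical folds (fine regions inherit their
  coarse parent's fold); train on fine censuses; score *raw* test-fold
  aggregates, so no test-region census enters the prediction. The
  pooled test set is identical to the coarse protocol's, making the
  two directly comparable.
* **Transfer** — train on the other landscapes with fine supervision
  (80/20 seeded region split for validation), deploy on the entire
  target landscape with no dasymetric adjustment, score at the
  target's fine level; repeated over seeded runs with mean ± sd.

Permutation importance shuffles one covariate channel across the
active cells (the cells the model reads), re-evaluates, and reports
the per-metric drop against the unshuffled baseline, averaged over
seeded repeats. A constant channel drops exactly zero.

## Synthetic landscapes

The simulator produces the statistical structure the method assumes,
not realistic geography:

* **Covariates**: per channel, white Gaussian noise convolved with an
  isotropic Gaussian kernel of the channel's correlation length
  (default 6, 4, 4, 3, 3, 2, 2, 2 cells), z-scored. Real covariate
  maps are spatially smooth; correlation lengths of a few hundred
  metres emulate that.
* **Buildings**: `Poisson(exp(1.5 * X_settlement + offset))`, the
  offset bisected so the expected built fraction hits the target
  (default 5%, inside the 3.4–7.5% range of real national datasets at
  this resolution); the realized fraction must land within ±20%
  relative. The settlement gain of 1.5 yields a heavy-tailed but not
  winner-take-all settlement system (largest fine-region count ≈ 25×
  the mean); stronger gains concentrate essentially all population in
  one cluster, which no real two-level census exhibits and which makes
  every fold containing it unpredictable.
* **Occupancy**: `softplus(w·X + bias)` plus optional truncated
  Gaussian noise floored at zero. The default weights
  `(0.4, 2.2, −1.5, 1.2, 0.9, −0.8, 0.5, 0.3)` put most of their mass
  on channels *other* than the settlement channel, so occupancy
  carries information building counts cannot supply — the regime the
  factorized model exists for — while the small positive settlement
  weight (urban cells slightly more crowded, as in real cities) keeps
  the occupancy field less variable than the population field on
  active cells. With zero noise the occupancy is an exact function of
  the covariates, which is the oracle behind the parameter-recovery
  tests.
* **Regions**: Voronoi partition around uniformly sampled seed cells;
  120 fine regions grouped into 10 coarse regions by nearest
  fine-centroid anchors (every coarse region contains at least its
  anchor's fine region). The 12:1 fine:coarse ratio sits inside the
  ~9–21 range of real two-level hierarchies; much smaller ratios make
  the coarse-level dasymetric constraint so tight that disaggregation
  quality stops depending on the model.
* **Censuses**: fine counts are the rounded per-region sums of true
  population; coarse counts are exact sums of their fine members, so
  the hierarchy invariant holds exactly and rounding never exceeds
  ±0.5 per fine region.
* **Landscape families** (for transfer): each additional landscape
  redraws all fields and perturbs the occupancy law — per-channel
  weight scaling `U(0.2, 1.8)` plus additive `N(0, 0.7)` jitter and
  bias jitter `N(0, 0.8)`. This is the covariate-shift mechanism that
  makes cross-landscape transfer genuinely harder than in-landscape
  supervision, as it is between real countries; identically
  distributed replicate landscapes would make transfer trivially easy.

Everything is a pure function of `(config, seed)`; one global seed
fans out to per-component streams via a CRC-based label hash, so each
stage is independently reproducible.

What passing tests on these landscapes do **not** show: robustness to
building-map omissions and spurious detections, to census
misalignment or undercounts, to non-stationary covariate semantics
across countries, or to covariates whose informativeness differs from
the synthetic linear-softplus law. The generator's distributional
choices are stand-ins, not estimates of any real country.

## Problem sizes and numerical choices

Default test scale: 128×128 cells (≈800 built), 120 fine / 10 coarse
regions, 8 channels. The expensive checks train with a reduced weight
decay grid `{0, 1e-4}` at 300 epochs (protocol comparisons) or
`{0}` at 120 epochs (ablation, importance), three seeds each — chosen
so a full test run and the acceptance script each complete in minutes
on one CPU core while leaving the qualitative orderings stable.

Normalization standard deviations are floored at 1e-6; covariate
no-data cells are imputed at the channel mean (zero after z-scoring),
flagged, and forced to zero population. Region id 0 is reserved for
"outside the study area" and never carries population; negative ids
are rejected. All rasters of a dataset must share shape and affine
placement exactly — nothing resamples. GeoTIFF I/O is implemented
with `tifffile`, writing ModelPixelScale / ModelTiepoint / GDAL_NODATA
tags and a JSON `ImageDescription` carrying the CRS tag and the
`adjusted` flag.

## Known limitations

* The ICM candidate set cannot move a cell off zero, and the search is
  local: the final configuration is a fixed point, not a global
  minimum.
* The region forest extrapolates poorly to pixels whose features lie
  far outside the range of region means (dense urban cells); the
  training-total calibration fixes global scale, not range
  compression. On these landscapes the forest trails the naive
  within-landscape rate baseline; its fine-vs-coarse supervision
  degradation and its gap to the occupancy model are the robust,
  tested directions.
* `fit_multi` supports multi-landscape training for the network
  heads; pseudo-region pairs are drawn within a landscape only.
* Uncertainty quantification, GPU execution, reprojection and vector
  rasterization are out of scope.
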