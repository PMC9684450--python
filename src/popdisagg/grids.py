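"""Core gridded data containers.

All rasters in a workflow share one :class:`GridSpec` (same shape, same
affine placement); nothing in this package resamples or reprojects, so
co-registration is checked eagerly and violations raise
:class:`CoRegistrationError`.

Conventions
-----------
* row-major grids, origin at the top-left (north-west) corner; cell
  ``(0, 0)`` is the north-west cell
* region id ``0`` means "outside the study area" and never carries
  population; negative region ids are invalid
* covariate no-data cells are flagged in a mask and imputed downstream;
  population is forced to zero there
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GridSpec",
    "CovariateStack",
    "BuildingCountMap",
    "RegionMap",
    "RegionHierarchy",
    "CensusTable",
    "PopulationMap",
    "CoRegistrationError",
    "ValidationError",
    "HierarchyError",
]


class ValidationError(ValueError):
    """A container violates one of its invariants."""


class CoRegistrationError(ValidationError):
    """Two rasters that must share a grid do not."""


class HierarchyError(ValidationError):
    """Fine/coarse region bookkeeping is inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: shape plus affine placement.

    ``cell_size`` is the ground sampling distance in metres (100 m for
    all the intended inputs). ``origin`` is the map coordinate of the
    top-left corner of the top-left cell.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError(f"grid shape must be >= 1x1, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise ValidationError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def compatible(self, other: "GridSpec") -> bool:
        """True if the two grids are exactly co-registered."""
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_compatible(self, other: "GridSpec", what: str = "raster") -> None:
        if not self.compatible(other):
            raise CoRegistrationError(
                f"{what} is not co-registered: {self.shape}@{self.origin} vs "
                f"{other.shape}@{other.origin}"
            )


def _check_grid_array(grid: GridSpec, arr: np.ndarray, name: str, ndim: int = 2) -> None:
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-D, got {arr.ndim}-D")
    if arr.shape[:2] != grid.shape:
        raise CoRegistrationError(f"{name} shape {arr.shape[:2]} != grid {grid.shape}")


@dataclass
class CovariateStack:
    """C co-registered covariate grids, ``values[row, col, channel]``.

    ``nodata_mask`` flags cells where at least one channel had no data;
    values there are imputed (channel mean, i.e. 0 after z-scoring) but
    predicted population is forced to zero.
    """

    grid: GridSpec
    channels: list[str]
    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_grid_array(self.grid, self.values, "covariate values", ndim=3)
        if self.values.shape[2] != len(self.channels):
            raise ValidationError(
                f"{self.values.shape[2]} value planes but {len(self.channels)} channel names"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("duplicate channel names")
        if len(self.channels) < 1:
            raise ValidationError("need at least one channel")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        _check_grid_array(self.grid, self.nodata_mask, "nodata mask")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValidationError("non-finite covariate values outside the nodata mask")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in stack {self.channels}") from None
        return self.values[:, :, idx]


@dataclass
class BuildingCountMap:
    """Per-cell building counts; cells with ``counts > 0`` are "active"."""

    grid: GridSpec
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        _check_grid_array(self.grid, self.counts, "building counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValidationError("building counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("negative building counts")

    @property
    def active_mask(self) -> np.ndarray:
        return self.counts > 0

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())


@dataclass
class RegionMap:
    """Integer region ids per cell; 0 = outside the study area."""

    grid: GridSpec
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        _check_grid_array(self.grid, self.ids, "region ids")
        if not np.issubdtype(self.ids.dtype, np.integer):
            raise ValidationError("region ids must be an integer array")
        if (self.ids < 0).any():
            raise ValidationError("negative region ids (0 is reserved for outside)")
        self.ids = self.ids.astype(np.int64)

    @property
    def in_study_mask(self) -> np.ndarray:
        return self.ids > 0

    def region_ids(self) -> np.ndarray:
        """Sorted unique positive ids present on the map."""
        u = np.unique(self.ids)
        return u[u > 0]


@dataclass(frozen=True)
class RegionHierarchy:
    """Mapping from fine region id to its enclosing coarse region id."""

    fine_to_coarse: dict[int, int]

    def __post_init__(self) -> None:
        for f, c in self.fine_to_coarse.items():
            if f <= 0 or c <= 0:
                raise HierarchyError(f"non-positive id in hierarchy: {f} -> {c}")

    def coarse_ids(self) -> list[int]:
        return sorted(set(self.fine_to_coarse.values()))

    def fine_ids(self) -> list[int]:
        return sorted(self.fine_to_coarse)

    def coarse_of(self, fine_id: int) -> int:
        try:
            return self.fine_to_coarse[fine_id]
        except KeyError:
            raise HierarchyError(f"fine region {fine_id} missing from hierarchy") from None

    def members(self, coarse_id: int) -> list[int]:
        return sorted(f for f, c in self.fine_to_coarse.items() if c == coarse_id)

    def coarsen_map(self, regions: RegionMap) -> RegionMap:
        """Relabel a fine-level region map to coarse ids."""
        out = np.zeros_like(regions.ids)
        for f, c in self.fine_to_coarse.items():
            out[regions.ids == f] = c
        missing = set(np.unique(regions.ids[regions.ids > 0]).tolist()) - set(self.fine_to_coarse)
        if missing:
            raise HierarchyError(f"fine ids {sorted(missing)} missing from hierarchy")
        return RegionMap(regions.grid, out)


@dataclass
class CensusTable:
    """Region id -> population count at one administrative level."""

    level: str
    entries: dict[int, float]
    warn_empty: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.level not in ("fine", "coarse"):
            raise ValidationError(f"level must be 'fine' or 'coarse', got {self.level!r}")
        clean: dict[int, float] = {}
        for rid, count in self.entries.items():
            rid = int(rid)
            if rid in clean:
                raise ValidationError(f"duplicate region id {rid}")
            if count < 0:
                raise ValidationError(f"negative population {count} for region {rid}")
            clean[rid] = float(count)
        self.entries = clean
        if not clean and self.warn_empty:
            import warnings

            warnings.warn("census table is empty", stacklevel=2)

    @property
    def n_c(self) -> int:
        return len(self.entries)

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))

    def counts_for(self, ids) -> np.ndarray:
        return np.array([self.entries[int(i)] for i in ids], dtype=np.float64)

    def subset(self, ids) -> "CensusTable":
        return CensusTable(self.level, {int(i): self.entries[int(i)] for i in ids})


@dataclass
class PopulationMap:
    """Per-cell population estimates (or truth); ``adjusted`` marks maps
    that were dasymetrically rescaled to match census totals."""

    grid: GridSpec
    values: np.ndarray
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_grid_array(self.grid, self.values, "population values")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite population values")
        if (self.values < 0).any():
            raise ValidationError("negative population values")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def with_values(self, values: np.ndarray, adjusted: bool | None = None) -> "PopulationMap":
        return replace(
            self, values=values, adjusted=self.adjusted if adjusted is None else adjusted
        )


def check_hierarchy_consistency(
    fine: CensusTable, coarse: CensusTable, hierarchy: RegionHierarchy
) -> None:
    """Assert that coarse counts equal the sum of their fine members exactly."""
    for cid in hierarchy.coarse_ids():
        if cid not in coarse.entries:
            raise HierarchyError(f"coarse region {cid} missing from coarse census")
        members = hierarchy.members(cid)
        s = sum(fine.entries.get(f, 0.0) for f in members)
        if s != coarse.entries[cid]:
            raise HierarchyError(
                f"coarse region {cid}: fine members sum to {s}, census says {coarse.entries[cid]}"
            )
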