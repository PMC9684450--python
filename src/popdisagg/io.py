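"""GeoTIFF and CSV input/output.

Rasters are single-band GeoTIFFs (float32 covariates/population, int32
region ids, uint16 building counts) written with ``tifffile``. The
affine placement goes into the standard GeoTIFF tags (ModelPixelScale,
ModelTiepoint), the nodata value into GDAL_NODATA, and a small JSON
blob with the CRS tag and flags into ImageDescription. Census tables
and the fine-to-coarse hierarchy are two-column CSV files.

All rasters of a dataset must be exactly co-registered; nothing here
resamples.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import (
    BuildingCountMap,
    CensusTable,
    CoRegistrationError,
    CovariateStack,
    GridSpec,
    HierarchyError,
    PopulationMap,
    RegionHierarchy,
    RegionMap,
    ValidationError,
    check_hierarchy_consistency,
)

__all__ = [
    "read_raster",
    "write_raster",
    "read_covariate_stack",
    "read_census_table",
    "write_census_table",
    "load_region_map",
    "write_population_raster",
    "read_population_raster",
    "write_landscape",
    "read_landscape",
]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_DEFAULT_NODATA = {"f": -99999.0, "i": -1, "u": 0}


def write_raster(
    path,
    array: np.ndarray,
    grid: GridSpec,
    nodata=None,
    nodata_mask: np.ndarray | None = None,
    meta: dict | None = None,
) -> None:
    """Write a single-band raster with GeoTIFF placement tags."""
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise CoRegistrationError(f"array shape {array.shape} != grid {grid.shape}")
    if nodata is None:
        nodata = _DEFAULT_NODATA[array.dtype.kind]
    out = array.copy()
    if nodata_mask is not None:
        out[nodata_mask] = nodata
    desc = {"crs_tag": grid.crs_tag}
    if meta:
        desc.update(meta)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin[0]), float(grid.origin[1]), 0.0)),
        (_TAG_GDAL_NODATA, "s", None, str(nodata)),
    ]
    tifffile.imwrite(str(path), out, description=json.dumps(desc), extratags=extratags)


def read_raster(path) -> tuple[np.ndarray, GridSpec, float, dict]:
    """Read a single-band raster; returns (array, grid, nodata, meta)."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        array = page.asarray()
        if array.ndim != 2:
            raise ValidationError(f"{path}: expected a single-band raster, got shape {array.shape}")
        tag = page.tags.get(_TAG_PIXEL_SCALE)
        cell = float(tag.value[0]) if tag is not None else 100.0
        tag = page.tags.get(_TAG_TIEPOINT)
        origin = (float(tag.value[3]), float(tag.value[4])) if tag is not None else (0.0, 0.0)
        tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = float(tag.value) if tag is not None else np.nan
        meta: dict = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (ValueError, TypeError):
                meta = {}
    grid = GridSpec(
        array.shape[0], array.shape[1], cell_size=cell, origin=origin,
        crs_tag=str(meta.get("crs_tag", "")),
    )
    return array, grid, nodata, meta


def read_covariate_stack(raster_paths, manifest: list[str]) -> CovariateStack:
    """Assemble co-registered single-band rasters into a covariate stack.

    ``manifest`` names the channels in order and must be as long as
    ``raster_paths``. Nodata cells (per the files' GDAL_NODATA value, or
    non-finite) are flagged in the stack mask and imputed with the
    channel mean of the valid cells.
    """
    raster_paths = list(raster_paths)
    if len(raster_paths) != len(manifest):
        raise ValidationError(
            f"{len(raster_paths)} rasters but manifest names {len(manifest)} channels"
        )
    if len(raster_paths) == 0:
        raise ValidationError("empty covariate manifest")
    planes, grid0 = [], None
    mask = None
    for path, name in zip(raster_paths, manifest):
        if not isinstance(name, str) or not name:
            raise ValidationError(f"bad manifest channel name {name!r}")
        arr, grid, nodata, _ = read_raster(path)
        arr = np.asarray(arr, dtype=np.float64)
        if grid0 is None:
            grid0 = grid
            mask = np.zeros(grid.shape, dtype=bool)
        else:
            grid0.require_compatible(grid, what=str(path))
        bad = ~np.isfinite(arr)
        if np.isfinite(nodata):
            bad |= arr == nodata
        if bad.any():
            valid = arr[~bad]
            arr = arr.copy()
            arr[bad] = valid.mean() if valid.size else 0.0
            mask |= bad
        planes.append(arr)
    values = np.stack(planes, axis=2)
    return CovariateStack(grid0, list(manifest), values, nodata_mask=mask)


def read_census_table(path, level: str) -> CensusTable:
    """Load a region_id,population CSV as a census table."""
    df = pd.read_csv(path)
    required = {"region_id", "population"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: census CSV needs columns {sorted(required)}")
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
        raise ValidationError(f"{path}: duplicate region ids {dup}")
    if (df["population"] < 0).any():
        raise ValidationError(f"{path}: negative population counts")
    entries = dict(zip(df["region_id"].astype(int), df["population"].astype(float)))
    return CensusTable(level, entries)


def write_census_table(table: CensusTable, path) -> None:
    pd.DataFrame(
        {"region_id": sorted(table.entries), "population": [table.entries[i] for i in sorted(table.entries)]}
    ).to_csv(path, index=False)


def load_region_map(raster_path, hierarchy_csv=None):
    """Load a region-id raster, optionally with a fine->coarse hierarchy.

    Returns ``(RegionMap, RegionHierarchy | None)``. Every positive id on
    the raster must appear in the hierarchy when one is supplied.
    """
    arr, grid, nodata, _ = read_raster(raster_path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError(f"{raster_path}: region raster must be integer-typed")
    ids = arr.astype(np.int64)
    if np.isfinite(nodata):
        ids[ids == int(nodata)] = 0
    regions = RegionMap(grid, ids)
    hierarchy = None
    if hierarchy_csv is not None:
        df = pd.read_csv(hierarchy_csv)
        if not {"fine_id", "coarse_id"}.issubset(df.columns):
            raise ValidationError(f"{hierarchy_csv}: hierarchy CSV needs fine_id,coarse_id")
        hierarchy = RegionHierarchy(dict(zip(df["fine_id"].astype(int), df["coarse_id"].astype(int))))
        present = set(regions.region_ids().tolist())
        missing = present - set(hierarchy.fine_to_coarse)
        if missing:
            raise HierarchyError(f"region ids {sorted(missing)} on raster missing from hierarchy")
    return regions, hierarchy


def write_population_raster(pop: PopulationMap, path) -> None:
    """Write a population map as float32 GeoTIFF; outside cells get nodata.

    The ``adjusted`` flag is recorded as metadata tag ``adjusted=1|0``.
    Outside cells are those with exactly zero population AND flagged via
    meta mask conventions upstream; here zero-valued cells are kept as 0
    and a nodata value is reserved for mask use by callers.
    """
    write_raster(
        path,
        pop.values.astype(np.float32),
        pop.grid,
        nodata=-99999.0,
        meta={"adjusted": 1 if pop.adjusted else 0},
    )


def read_population_raster(path) -> PopulationMap:
    arr, grid, nodata, meta = read_raster(path)
    arr = np.asarray(arr, dtype=np.float64)
    arr[arr == nodata] = 0.0
    return PopulationMap(grid, arr, adjusted=bool(meta.get("adjusted", 0)))


def write_landscape(truth, out_dir) -> None:
    """Write a full synthetic landscape as GeoTIFF + CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = truth.covariates.grid
    for i, name in enumerate(truth.covariates.channels):
        write_raster(out / f"covariate_{i:02d}_{name}.tif",
                     truth.covariates.values[:, :, i].astype(np.float32), grid)
    (out / "manifest.json").write_text(json.dumps(truth.covariates.channels))
    write_raster(out / "buildings.tif", truth.buildings.counts.astype(np.uint16), grid, nodata=0)
    write_raster(out / "regions.tif", truth.regions.ids.astype(np.int32), grid, nodata=-1)
    write_raster(out / "occupancy_true.tif", truth.true_occupancy.astype(np.float32), grid)
    write_population_raster(truth.true_population, out / "population_true.tif")
    write_census_table(truth.census_fine, out / "census_fine.csv")
    write_census_table(truth.census_coarse, out / "census_coarse.csv")
    pd.DataFrame(
        sorted(truth.hierarchy.fine_to_coarse.items()), columns=["fine_id", "coarse_id"]
    ).to_csv(out / "hierarchy.csv", index=False)


def read_landscape(in_dir):
    """Read back a directory written by :func:`write_landscape`."""
    from .synthetic import SyntheticTruth

    p = Path(in_dir)
    manifest = json.loads((p / "manifest.json").read_text())
    paths = sorted(p.glob("covariate_*.tif"))
    stack = read_covariate_stack(paths, manifest)
    barr, bgrid, _, _ = read_raster(p / "buildings.tif")
    stack.grid.require_compatible(bgrid, "buildings.tif")
    buildings = BuildingCountMap(stack.grid, barr.astype(np.int64))
    regions, hierarchy = load_region_map(p / "regions.tif", p / "hierarchy.csv")
    stack.grid.require_compatible(regions.grid, "regions.tif")
    occ, _, _, _ = read_raster(p / "occupancy_true.tif")
    pop = read_population_raster(p / "population_true.tif")
    census_fine = read_census_table(p / "census_fine.csv", "fine")
    census_coarse = read_census_table(p / "census_coarse.csv", "coarse")
    check_hierarchy_consistency(census_fine, census_coarse, hierarchy)
    return SyntheticTruth(
        covariates=stack,
        buildings=buildings,
        true_occupancy=np.asarray(occ, dtype=np.float64),
        true_population=pop,
        regions=regions,
        hierarchy=hierarchy,
        census_fine=census_fine,
        census_coarse=census_coarse,
    )
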