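"""Core domain types and I/O: plot tables, rasters, the 500 km tile grid and
uint16 sentinel encoding.

All geometry lives in a projected equal-area CRS in metres (ETRS89-LAEA,
EPSG:3035, by default). Rasters are plain north-up grids; the only transform
this package needs is an origin plus a square pixel size, so no general
affine machinery is pulled in. GeoTIFF files are read and written with
tifffile, carrying the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory) plus GDAL's nodata tag so downstream GIS tools pick up
georeferencing and nodata correctly.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

# ---------------------------------------------------------------------------
# Constants and error types
# ---------------------------------------------------------------------------

DEFAULT_EPSG = 3035  # ETRS89-extended / LAEA Europe

TILE_SIZE = 500_000  # m, output tile extent
#: The 500 km tile grid is anchored so that a corner falls on E 3 900 000 /
#: N 2 400 000 (tile E39_N24); corners are multiples of 100 km but not of
#: 500 km, hence the 400 km anchor offset.
TILE_ANCHOR = 400_000

#: Output layer names, fixed: attribute and uncertainty layer per variable.
VARIABLES = (
    "Vol",
    "stdev_vol",
    "AGB",
    "stdev_agb",
    "P_agb_conifers",
    "stdev_P_agb_conifers",
)

#: uint16 sentinel codes shared by all output layers.
NODATA_CODE = 65535
NONFOREST_CODE = 65534
MAX_VALUE_CODE = 65533

#: Forest-type raster categories (Copernicus HRL convention).
FTY_NONFOREST = 0
FTY_BROADLEAVED = 1
FTY_CONIFEROUS = 2

PLOT_COLUMNS = ("plot_id", "easting", "northing", "year", "country", "vol", "agb", "dcp")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class TableParseError(ValueError):
    """A table cell could not be parsed as the required type."""


class ConfigError(ValueError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridTransform:
    """North-up raster georeferencing: top-left corner and square pixel size."""

    origin_e: float  # easting of the top-left corner (m)
    origin_n: float  # northing of the top-left corner (m)
    pixel: float  # cell size (m)

    def xy(self, row: int | np.ndarray, col: int | np.ndarray):
        """Centre coordinates of pixel (row, col)."""
        e = self.origin_e + (np.asarray(col) + 0.5) * self.pixel
        n = self.origin_n - (np.asarray(row) + 0.5) * self.pixel
        return e, n

    def rowcol(self, e: float, n: float) -> tuple[int, int]:
        """Pixel containing point (e, n); half-open cell membership."""
        col = math.floor((e - self.origin_e) / self.pixel)
        row = math.floor((self.origin_n - n) / self.pixel)
        return row, col

    def pixel_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of a pixel's footprint."""
        x0 = self.origin_e + col * self.pixel
        y1 = self.origin_n - row * self.pixel
        return x0, y1 - self.pixel, x0 + self.pixel, y1

    def extent(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        h, w = shape
        return (
            self.origin_e,
            self.origin_n - h * self.pixel,
            self.origin_e + w * self.pixel,
            self.origin_n,
        )


# ---------------------------------------------------------------------------
# Tiling grid and output naming
# ---------------------------------------------------------------------------


def tile_corner_for(easting: float, northing: float) -> tuple[int, int]:
    """Lower-left corner (m) of the 500 km tile containing a point.

    Tiles are half-open squares [corner, corner + 500 km) in both axes, so a
    corner belongs to the tile it names.
    """
    ce = math.floor((easting - TILE_ANCHOR) / TILE_SIZE) * TILE_SIZE + TILE_ANCHOR
    cn = math.floor((northing - TILE_ANCHOR) / TILE_SIZE) * TILE_SIZE + TILE_ANCHOR
    return int(ce), int(cn)


def tile_id_for(easting: float, northing: float) -> str:
    """Tile label ``E{ee}_N{nn}`` with corners in units of 100 km."""
    ce, cn = tile_corner_for(easting, northing)
    return f"E{int(ce / 100_000)}_N{int(cn / 100_000)}"


_TILE_RE = re.compile(r"^E(-?\d+)_N(-?\d+)$")


def parse_tile_id(tile: str) -> tuple[int, int]:
    """Inverse of :func:`tile_id_for`: label -> lower-left corner in metres."""
    m = _TILE_RE.match(tile)
    if m is None:
        raise ValueError(f"not a tile label: {tile!r}")
    return int(m.group(1)) * 100_000, int(m.group(2)) * 100_000


@dataclass(frozen=True)
class MapTileSpec:
    """Identity of one output map file: year, variable and 500 km tile."""

    year: int
    variable: str
    tile_e: int  # lower-left corner easting / 100 km
    tile_n: int  # lower-left corner northing / 100 km

    def __post_init__(self):
        if self.variable not in VARIABLES:
            raise ValueError(
                f"unknown output variable {self.variable!r}; expected one of {VARIABLES}"
            )

    @property
    def tile(self) -> str:
        return f"E{self.tile_e}_N{self.tile_n}"

    @property
    def corner(self) -> tuple[int, int]:
        """Lower-left corner in metres."""
        return self.tile_e * 100_000, self.tile_n * 100_000


def output_filename(spec: MapTileSpec) -> str:
    """``{year}_{variable}_{tile}.tif`` naming of output map files."""
    return f"{spec.year}_{spec.variable}_{spec.tile}.tif"


_FILENAME_RE = re.compile(r"^(\d+)_(.+)_E(-?\d+)_N(-?\d+)\.tif$")


def parse_output_filename(name: str) -> MapTileSpec:
    m = _FILENAME_RE.match(name)
    if m is None:
        raise ValueError(f"not an output map filename: {name!r}")
    return MapTileSpec(
        year=int(m.group(1)),
        variable=m.group(2),
        tile_e=int(m.group(3)),
        tile_n=int(m.group(4)),
    )


# ---------------------------------------------------------------------------
# uint16 sentinel encoding
# ---------------------------------------------------------------------------


def encode_uint16(
    values: np.ndarray, forest_mask: np.ndarray, valid_mask: np.ndarray
) -> np.ndarray:
    """Encode a physical-unit grid into the uint16 output convention.

    Invalid cells -> 65535 (nodata); valid non-forest cells -> 65534; valid
    forest cells -> value rounded half away from zero, clamped to
    [0, 65533]. Negative physical values are an upstream bug (predictions are
    convex combinations of non-negative responses) and raise.
    """
    values = np.asarray(values)
    forest_mask = np.asarray(forest_mask, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if not (values.shape == forest_mask.shape == valid_mask.shape):
        raise ValueError("values and masks must share shape")
    out = np.full(values.shape, NODATA_CODE, dtype=np.uint16)
    out[valid_mask & ~forest_mask] = NONFOREST_CODE
    use = valid_mask & forest_mask
    v = values[use].astype(np.float64)
    if np.any(~np.isfinite(v)):
        raise ValueError("non-finite physical value in a valid forest cell")
    if np.any(v < 0):
        raise ValueError("negative physical value in a valid forest cell")
    # round half away from zero; v >= 0 so floor(v + 0.5) does it
    enc = np.minimum(np.floor(v + 0.5), MAX_VALUE_CODE)
    out[use] = enc.astype(np.uint16)
    return out


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile + GeoTIFF tags)
# ---------------------------------------------------------------------------

_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


def _geotiff_extratags(transform: GridTransform, epsg: int, nodata) -> list:
    geokeys = (
        1, 1, 0, 3,  # directory header: version, revision, minor, key count
        1024, 0, 1, 1,  # GTModelType = projected
        1025, 0, 1, 1,  # GTRasterType = PixelIsArea
        3072, 0, 1, int(epsg),  # ProjectedCSType
    )
    tags = [
        (_TAG_PIXELSCALE, "d", 3, (float(transform.pixel), float(transform.pixel), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(transform.origin_e), float(transform.origin_n), 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
    ]
    if nodata is not None:
        tags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    return tags


def write_geotiff(
    path: str | Path,
    array: np.ndarray,
    transform: GridTransform,
    epsg: int = DEFAULT_EPSG,
    nodata=None,
) -> Path:
    """Write a single-band georeferenced GeoTIFF."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(array),
        photometric="minisblack",
        extratags=_geotiff_extratags(transform, epsg, nodata),
        software=None,
    )
    return path


def read_geotiff(path: str | Path):
    """Read a single-band GeoTIFF -> (array, GridTransform, epsg, nodata)."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        array = page.asarray()
        tags = page.tags
        scale = tags[_TAG_PIXELSCALE].value
        tie = tags[_TAG_TIEPOINT].value
        transform = GridTransform(origin_e=tie[3], origin_n=tie[4], pixel=scale[0])
        epsg = None
        if _TAG_GEOKEYS in tags:
            keys = tags[_TAG_GEOKEYS].value
            for i in range(4, len(keys), 4):
                if keys[i] == 3072:
                    epsg = int(keys[i + 3])
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            nodata = float(raw) if "." in raw or "e" in raw.lower() else int(raw)
    return array, transform, epsg, nodata


def write_map_tile(
    spec: MapTileSpec,
    array: np.ndarray,
    out_dir: str | Path,
    transform: GridTransform | None = None,
    epsg: int | None = DEFAULT_EPSG,
) -> Path:
    """Write one encoded output layer as a uint16 GeoTIFF named per convention.

    At full scale a tile is 50 000 x 50 000 cells covering the 500 km square;
    a reduced-extent mode (any shape, explicit ``transform``) writes small
    windows with correct georeferencing for testing.
    """
    array = np.asarray(array)
    if array.dtype != np.uint16:
        raise ValueError("map tiles must be uint16-encoded (see encode_uint16)")
    if epsg is None:
        raise ConfigError("output CRS (EPSG code) missing from configuration")
    if transform is None:
        ce, cn = spec.corner
        pixel = TILE_SIZE / array.shape[1]
        transform = GridTransform(origin_e=ce, origin_n=cn + array.shape[0] * pixel, pixel=pixel)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return write_geotiff(
        out_dir / output_filename(spec), array, transform, epsg=epsg, nodata=NODATA_CODE
    )


# ---------------------------------------------------------------------------
# Raster stacks
# ---------------------------------------------------------------------------

#: Band names of the 10 m input stack, in canonical order.
STACK_BANDS = ("B2", "B3", "B4", "B5", "B8", "B11", "B12", "TCD", "FTY", "QUALITY")
SPECTRAL_BANDS = ("B2", "B3", "B4", "B5", "B8", "B11", "B12")


@dataclass
class RasterStack:
    """Co-registered 10 m input layers plus the 30 m canopy-loss layer.

    ``bands`` holds the seven spectral bands, TCD (0-100 %), FTY
    (categorical) and the composite QUALITY band on one shared 10 m grid.
    ``gfc`` is the canopy-loss-year grid (0 = no loss) on its own 30 m
    transform. ``nodata`` maps band name -> nodata value (may be NaN).
    """

    bands: dict[str, np.ndarray]
    transform: GridTransform
    gfc: np.ndarray
    gfc_transform: GridTransform
    epsg: int = DEFAULT_EPSG
    nodata: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        shapes = {name: arr.shape for name, arr in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"10 m bands disagree in shape: {shapes}")
        missing = [b for b in STACK_BANDS if b not in self.bands]
        if missing:
            raise ValueError(f"stack missing bands: {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["B2"].shape

    def band_nodata(self, name: str):
        return self.nodata.get(name)


def write_raster_stack(stack: RasterStack, out_dir: str | Path) -> Path:
    """Write a stack as per-band GeoTIFFs plus a small JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.bands.items():
        write_geotiff(
            out_dir / f"{name}.tif", arr, stack.transform, epsg=stack.epsg,
            nodata=stack.nodata.get(name),
        )
    write_geotiff(
        out_dir / "GFC.tif", stack.gfc, stack.gfc_transform, epsg=stack.epsg,
        nodata=stack.nodata.get("GFC"),
    )
    manifest = {"epsg": stack.epsg, "bands": list(stack.bands)}
    (out_dir / "stack.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def read_raster_stack(path: str | Path) -> RasterStack:
    path = Path(path)
    manifest = json.loads((path / "stack.json").read_text())
    bands, nodata = {}, {}
    transform = epsg = None
    for name in manifest["bands"]:
        arr, transform, epsg, nd = read_geotiff(path / f"{name}.tif")
        bands[name] = arr
        if nd is not None:
            nodata[name] = nd
    gfc, gfc_transform, _, gfc_nd = read_geotiff(path / "GFC.tif")
    if gfc_nd is not None:
        nodata["GFC"] = gfc_nd
    return RasterStack(
        bands=bands, transform=transform, gfc=gfc, gfc_transform=gfc_transform,
        epsg=epsg if epsg is not None else manifest["epsg"], nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Plot tables
# ---------------------------------------------------------------------------

_NUMERIC_PLOT_COLUMNS = ("easting", "northing", "year", "vol", "agb", "dcp")


def validate_plot_table(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Validate plot records; return (valid rows, row-level diagnostics).

    Rows violating the domain invariants (negative vol/agb, dcp outside
    [0, 100], non-finite values, duplicated plot_id) are dropped and reported.
    """
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plot table missing required columns: {missing}")
    df = df.copy()
    bad_parse: list[str] = []
    for col in _NUMERIC_PLOT_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        failed = df.index[converted.isna() & df[col].notna()]
        if len(failed):
            bad_parse.append(f"column {col!r}: non-numeric rows {list(failed)}")
        df[col] = converted
    if bad_parse:
        raise TableParseError("; ".join(bad_parse))

    diagnostics: list[str] = []
    keep = pd.Series(True, index=df.index)

    def _flag(mask: pd.Series, reason: str):
        for idx in df.index[mask & keep]:
            diagnostics.append(f"row {idx} (plot_id={df.at[idx, 'plot_id']!r}): {reason}")
        keep[mask] = False

    finite = df[list(_NUMERIC_PLOT_COLUMNS)].apply(np.isfinite).all(axis=1)
    _flag(~finite, "non-finite attribute")
    _flag(df["vol"] < 0, "vol must be >= 0")
    _flag(df["agb"] < 0, "agb must be >= 0")
    _flag((df["dcp"] < 0) | (df["dcp"] > 100), "dcp must lie in [0, 100]")
    dup = df["plot_id"].duplicated(keep="first") & keep
    _flag(dup, "duplicate plot_id")
    out = df[keep].copy()
    out["plot_id"] = out["plot_id"].astype(str)
    out["year"] = out["year"].astype(int)
    return out, diagnostics


def read_plot_table(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a CSV plot table and validate it. See :func:`validate_plot_table`."""
    return validate_plot_table(pd.read_csv(path))


def write_plot_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
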