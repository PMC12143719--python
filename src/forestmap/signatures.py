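"""Plot-signature extraction and screening.

Each field plot contributes a circular footprint of 100 m² centred on its
coordinates. Continuous layers (spectral bands, TCD, composite quality) are
summarised by the area-weighted mean over the pixels the circle touches;
categorical layers (FTY, canopy-loss year) by the weighted mode, the category
with the greatest summed weight. The canopy-loss layer is extracted against
its native 30 m grid with the same circle.

Two screening rules then partition the plots: composite quality must exceed
4000 (cloud screening), and plots with detected canopy loss in or after
min(2018, earliest measurement year - 1) are dropped as changed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from .core import GridTransform, RasterStack

#: Radius of the 100 m² circular plot footprint.
FOOTPRINT_AREA = 100.0  # m²
FOOTPRINT_RADIUS = math.sqrt(FOOTPRINT_AREA / math.pi)  # ~5.6419 m

QUALITY_THRESHOLD = 4000
CHANGE_PIVOT_YEAR = 2018

STATUS_KEPT = "kept"
STATUS_CLOUD = "excluded_cloud"
STATUS_CHANGE = "excluded_change"
STATUS_OFFGRID = "excluded_offgrid"

#: Signature column -> (stack layer, aggregation) mapping.
SIGNATURE_MEANS = {
    "b2": "B2", "b3": "B3", "b4": "B4", "b5": "B5",
    "b8": "B8", "b11": "B11", "b12": "B12",
    "tcd": "TCD", "quality": "QUALITY",
}


class FootprintOffGrid(Exception):
    """The plot circle extends beyond the raster extent."""


@dataclass(frozen=True)
class FootprintWeights:
    """Pixels intersecting the plot circle with area-fraction weights.

    Weights are the fraction of the circle's area falling in each pixel,
    normalised to sum to 1.
    """

    rows: np.ndarray
    cols: np.ndarray
    weights: np.ndarray


def circle_footprint(
    center: tuple[float, float],
    transform: GridTransform,
    shape: tuple[int, int],
    radius: float = FOOTPRINT_RADIUS,
    quad_segs: int = 64,
) -> FootprintWeights:
    """Area-fraction weights of the pixels covering a circle.

    The circle is approximated by a polygon with ``4 * quad_segs`` vertices
    (256 by default) and intersected with each candidate pixel square; the
    tiny area deficit of the polygonal approximation cancels in the
    normalisation. Raises :class:`FootprintOffGrid` when the circle is not
    fully inside the raster extent.
    """
    e, n = center
    xmin, ymin, xmax, ymax = transform.extent(shape)
    if e - radius < xmin or e + radius > xmax or n - radius < ymin or n + radius > ymax:
        raise FootprintOffGrid(f"footprint at ({e}, {n}) leaves the raster extent")
    circle = Point(e, n).buffer(radius, quad_segs=quad_segs)
    r0, c0 = transform.rowcol(e - radius, n + radius)
    r1, c1 = transform.rowcol(e + radius, n - radius)
    rows, cols, areas = [], [], []
    for row in range(max(r0, 0), min(r1, shape[0] - 1) + 1):
        for col in range(max(c0, 0), min(c1, shape[1] - 1) + 1):
            a = circle.intersection(box(*_pixel_box(transform, row, col))).area
            if a > 0.0:
                rows.append(row)
                cols.append(col)
                areas.append(a)
    w = np.asarray(areas, dtype=np.float64)
    return FootprintWeights(
        rows=np.asarray(rows, dtype=np.intp),
        cols=np.asarray(cols, dtype=np.intp),
        weights=w / w.sum(),
    )


def _pixel_box(transform: GridTransform, row: int, col: int):
    x0, y0, x1, y1 = transform.pixel_bounds(row, col)
    return x0, y0, x1, y1


def weighted_mean(band: np.ndarray, fw: FootprintWeights, nodata=None) -> float:
    """Footprint-weighted mean of a continuous band; NaN if any contributing
    pixel is nodata (the signature is invalid for that band)."""
    vals = np.asarray(band)[fw.rows, fw.cols].astype(np.float64)
    if _any_nodata(vals, nodata):
        return float("nan")
    return float(np.dot(fw.weights, vals))


def weighted_mode(band: np.ndarray, fw: FootprintWeights, nodata=None) -> float:
    """Footprint-weighted mode of a categorical band: the category with the
    greatest summed weight; exact ties break to the lowest category code.
    NaN if every contributing pixel is nodata."""
    vals = np.asarray(band)[fw.rows, fw.cols].astype(np.float64)
    ok = ~_nodata_mask(vals, nodata)
    if not ok.any():
        return float("nan")
    cats, inverse = np.unique(vals[ok], return_inverse=True)
    sums = np.zeros(len(cats))
    np.add.at(sums, inverse, fw.weights[ok])
    # argmax returns the first maximum; cats is sorted ascending, so ties
    # resolve to the lowest code
    return float(cats[np.argmax(sums)])


def _nodata_mask(vals: np.ndarray, nodata) -> np.ndarray:
    mask = ~np.isfinite(vals)
    if nodata is not None and np.isfinite(nodata):
        mask |= vals == nodata
    return mask


def _any_nodata(vals: np.ndarray, nodata) -> bool:
    return bool(_nodata_mask(vals, nodata).any())


def extract_signatures(
    plots: pd.DataFrame, stack: RasterStack, quad_segs: int = 64
) -> pd.DataFrame:
    """Extract the raster covariates of every plot.

    Returns the plot table extended with the signature columns (b2..b12, tcd,
    quality, fty, gfc_loss_year) and a preliminary ``screen_status``:
    ``excluded_offgrid`` for plots whose footprint leaves the raster or
    touches nodata in any 10 m layer, ``kept`` otherwise (the quality and
    change screens are applied by :func:`screen_plots`).
    """
    records = []
    sig_cols = list(SIGNATURE_MEANS) + ["fty", "gfc_loss_year"]
    for rec in plots.itertuples(index=False):
        row: dict = {c: getattr(rec, c) for c in plots.columns}
        try:
            fw = circle_footprint(
                (rec.easting, rec.northing), stack.transform, stack.shape,
                quad_segs=quad_segs,
            )
            fw30 = circle_footprint(
                (rec.easting, rec.northing), stack.gfc_transform, stack.gfc.shape,
                quad_segs=quad_segs,
            )
        except FootprintOffGrid:
            row.update({c: float("nan") for c in sig_cols})
            row["screen_status"] = STATUS_OFFGRID
            records.append(row)
            continue
        for col, band in SIGNATURE_MEANS.items():
            row[col] = weighted_mean(stack.bands[band], fw, stack.band_nodata(band))
        row["fty"] = weighted_mode(stack.bands["FTY"], fw, stack.band_nodata("FTY"))
        row["gfc_loss_year"] = weighted_mode(stack.gfc, fw30, stack.band_nodata("GFC"))
        bad = any(not np.isfinite(row[c]) for c in sig_cols)
        row["screen_status"] = STATUS_OFFGRID if bad else STATUS_KEPT
        records.append(row)
    return pd.DataFrame.from_records(records)


def screen_plots(
    signatures: pd.DataFrame,
    earliest_year: int | None = None,
    quality_threshold: float = QUALITY_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cloud and canopy-change screens.

    A plot is ``excluded_cloud`` unless its footprint quality strictly
    exceeds ``quality_threshold``, and ``excluded_change`` when its
    canopy-loss year is >= min(2018, earliest_year - 1) (loss year 0 means
    no recorded loss and always passes). Pure filter: no record is altered
    beyond ``screen_status``, and kept + excluded partition the input.
    """
    if earliest_year is None:
        earliest_year = int(signatures["year"].min())
    pivot = min(CHANGE_PIVOT_YEAR, earliest_year - 1)
    out = signatures.copy()
    usable = out["screen_status"] != STATUS_OFFGRID
    cloudy = usable & ~(out["quality"] > quality_threshold)
    out.loc[cloudy, "screen_status"] = STATUS_CLOUD
    changed = usable & ~cloudy & (out["gfc_loss_year"] > 0) & (out["gfc_loss_year"] >= pivot)
    out.loc[changed, "screen_status"] = STATUS_CHANGE
    counts = out["screen_status"].value_counts().to_dict()
    for status in (STATUS_KEPT, STATUS_CLOUD, STATUS_CHANGE, STATUS_OFFGRID):
        counts.setdefault(status, 0)
    return out, counts
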