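"""Training-set assembly: processing-area plot pooling, the deterministic
every-third validation split, location features and feature standardisation.

A processing area is a multi-country block mapped with one pooled set of
training plots. Where the area itself holds plots, 1 km grid locations
(eastings/northings floored to the km) enter the feature space so that
spatially close plots are preferred as neighbours; plot-free areas borrow
plots from ecologically similar countries and drop the location features
(or keep only northing, the one documented exception).

Features are, in fixed column order: the seven spectral bands, TCD, FTY as a
single binary indicator (coniferous = 1, broadleaved = 0; plots with a
non-forest signature are excluded from training), then optionally the 1 km
easting and/or northing. "Equal feature weights" is realised by
standardising every column to zero mean / unit variance on the mapping plots
(``scaling="standardize"``); raw units are available via ``scaling="none"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigError, FTY_BROADLEAVED, FTY_CONIFEROUS

LOCATION_MODES = ("both_axes", "northing_only", "none")
BASE_FEATURES = ("B2", "B3", "B4", "B5", "B8", "B11", "B12", "TCD", "FTY")
_SIGNATURE_FOR_FEATURE = {
    "B2": "b2", "B3": "b3", "B4": "b4", "B5": "b5",
    "B8": "b8", "B11": "b11", "B12": "b12", "TCD": "tcd",
}
RESPONSES = ("vol", "agb", "dcp")


@dataclass(frozen=True)
class AreaConfig:
    """One processing area: member tiles, plot sourcing and location usage."""

    area_id: str
    member_tiles: tuple[str, ...] = ()
    contributing_countries: tuple[str, ...] = ()
    location_mode: str = "both_axes"

    def __post_init__(self):
        if self.location_mode not in LOCATION_MODES:
            raise ConfigError(
                f"area {self.area_id}: location_mode must be one of {LOCATION_MODES}"
            )

    def feature_columns(self) -> list[str]:
        cols = list(BASE_FEATURES)
        if self.location_mode == "both_axes":
            cols += ["E1KM", "N1KM"]
        elif self.location_mode == "northing_only":
            cols += ["N1KM"]
        return cols


def snap_to_1km_grid(easting, northing):
    """Floor coordinates to the origin of their 1 km grid cell."""
    return (
        np.floor(np.asarray(easting, dtype=np.float64) / 1000.0) * 1000.0,
        np.floor(np.asarray(northing, dtype=np.float64) / 1000.0) * 1000.0,
    )


def split_validation(plots: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic every-third split into mapping and validation sets.

    Plots are sorted ascending by volume (ties broken by plot_id) and every
    third plot — 1-based positions 3, 6, 9, ... — goes to validation, so the
    validation set holds floor(n/3) plots. The split depends only on the set
    of plots, not on input order.
    """
    if len(plots) < 3:
        warnings.warn("fewer than 3 plots: validation set is empty", stacklevel=2)
    s = plots.sort_values(["vol", "plot_id"], kind="mergesort").reset_index(drop=True)
    pos = np.arange(1, len(s) + 1)
    is_val = pos % 3 == 0
    return s[~is_val].reset_index(drop=True), s[is_val].reset_index(drop=True)


def pool_plots_for_area(
    area: AreaConfig, tables: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Concatenate the (mapping) plots of every contributing country.

    Plots appearing in several overlapping tiles stay as distinct rows — the
    pool is a plain concatenation, matching the production practice of using
    some plots more than once.
    """
    missing = [c for c in area.contributing_countries if c not in tables]
    if missing:
        raise ConfigError(
            f"area {area.area_id}: no plot table for countries {missing}"
        )
    parts = [tables[c] for c in area.contributing_countries]
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class FeatureScaler:
    """Per-column center/scale fitted on mapping plots only."""

    columns: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    mode: str = "standardize"

    def transform(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=np.float64)
        if raw.shape[-1] != len(self.columns):
            raise ValueError(
                f"expected {len(self.columns)} feature columns, got {raw.shape[-1]}"
            )
        return (raw - self.center) / self.scale


@dataclass
class TrainingSet:
    """Standardised feature matrix X, response matrix Y and their provenance."""

    X: np.ndarray
    Y: np.ndarray  # columns: vol, agb, dcp
    scaler: FeatureScaler
    plot_ids: np.ndarray
    columns: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        self.columns = self.scaler.columns


def raw_feature_matrix(plots: pd.DataFrame, area: AreaConfig) -> np.ndarray:
    """Assemble the raw (unscaled) feature matrix in the fixed column order.

    Rows with a non-forest FTY signature must be removed beforehand
    (see :func:`build_feature_matrix`).
    """
    cols = area.feature_columns()
    n = len(plots)
    out = np.empty((n, len(cols)), dtype=np.float64)
    e1km, n1km = snap_to_1km_grid(plots["easting"].to_numpy(), plots["northing"].to_numpy())
    for j, c in enumerate(cols):
        if c == "FTY":
            fty = plots["fty"].to_numpy()
            if not np.isin(fty, (FTY_CONIFEROUS, FTY_BROADLEAVED)).all():
                raise ValueError("FTY feature requires coniferous/broadleaved signatures only")
            out[:, j] = (fty == FTY_CONIFEROUS).astype(np.float64)
        elif c == "E1KM":
            out[:, j] = e1km
        elif c == "N1KM":
            out[:, j] = n1km
        else:
            sig = _SIGNATURE_FOR_FEATURE[c]
            vals = plots[sig].to_numpy(dtype=np.float64)
            if np.isnan(vals).any():
                bad = plots["plot_id"].to_numpy()[np.isnan(vals)][:5]
                raise ValueError(f"missing signature {sig!r} for plots {list(bad)}")
            out[:, j] = vals
    return out


def drop_nonforest(plots: pd.DataFrame) -> pd.DataFrame:
    """Remove plots whose FTY signature is non-forest (untrainable)."""
    return plots[np.isin(plots["fty"].to_numpy(), (FTY_CONIFEROUS, FTY_BROADLEAVED))].copy()


def build_feature_matrix(
    plots: pd.DataFrame, area: AreaConfig, scaling: str = "standardize"
) -> TrainingSet:
    """Build the standardized TrainingSet from pooled mapping plots.

    The scaler (per-column mean and standard deviation) is fitted on these
    mapping plots only; validation plots and map pixels are later transformed
    with the same scaler, never refitted. A zero-variance column keeps scale
    1 with a warning.
    """
    if scaling not in ("standardize", "none"):
        raise ConfigError(f"unknown scaling mode {scaling!r}")
    plots = drop_nonforest(plots)
    raw = raw_feature_matrix(plots, area)
    cols = tuple(area.feature_columns())
    if scaling == "standardize":
        center = raw.mean(axis=0)
        scale = raw.std(axis=0)
        zero = scale == 0.0
        if zero.any():
            names = [c for c, z in zip(cols, zero) if z]
            warnings.warn(f"zero-variance feature columns {names}: scale set to 1", stacklevel=2)
            scale = np.where(zero, 1.0, scale)
    else:
        center = np.zeros(raw.shape[1])
        scale = np.ones(raw.shape[1])
    scaler = FeatureScaler(columns=cols, center=center, scale=scale, mode=scaling)
    Y = plots[list(RESPONSES)].to_numpy(dtype=np.float64)
    return TrainingSet(
        X=scaler.transform(raw),
        Y=Y,
        scaler=scaler,
        plot_ids=plots["plot_id"].to_numpy(dtype=object),
    )
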