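"""Wall-to-wall map production: per-pixel features, tiled kNN prediction,
forest masking and encoded GeoTIFF output.

Features are evaluated at pixel centres with the same column layout as the
training plots; location features are the centre coordinates snapped to the
1 km grid. A pixel is predicted only when every input layer is valid there,
its composite quality exceeds the cloud threshold, and the forest-type layer
marks it as forest; non-forest pixels become the 65534 sentinel, everything
else 65535. Processing is windowed over row blocks — predictions are
per-pixel independent, so windowed and whole-array runs agree exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import (
    ConfigError,
    FTY_BROADLEAVED,
    FTY_CONIFEROUS,
    MapTileSpec,
    RasterStack,
    VARIABLES,
    encode_uint16,
    tile_id_for,
    write_map_tile,
)
from .knn import KnnConfig, KnnModel
from .signatures import QUALITY_THRESHOLD
from .training import AreaConfig, snap_to_1km_grid

#: Output layer name for each (response, kind) pair, in response order.
RESPONSE_LAYERS = (("Vol", "stdev_vol"), ("AGB", "stdev_agb"),
                   ("P_agb_conifers", "stdev_P_agb_conifers"))


@dataclass
class PredictionTile:
    """Predicted grids (physical units) plus validity and forest masks.

    ``layers`` maps the six output variable names to float32 grids; cells
    outside valid & forest are NaN.
    """

    layers: dict[str, np.ndarray]
    valid_mask: np.ndarray
    forest_mask: np.ndarray

    def counts(self) -> dict[str, int]:
        value = int((self.valid_mask & self.forest_mask).sum())
        nonforest = int((self.valid_mask & ~self.forest_mask).sum())
        total = self.valid_mask.size
        return {
            "value": value,
            "nonforest": nonforest,
            "nodata": total - value - nonforest,
            "total": total,
        }


def pixel_features(
    stack: RasterStack,
    area: AreaConfig,
    row0: int = 0,
    row1: int | None = None,
    quality_threshold: float = QUALITY_THRESHOLD,
):
    """Raw feature rows for the pixels of a row window.

    Returns (features, valid_mask, forest_mask); features has one row per
    window pixel in row-major order, NaN where invalid. A pixel is invalid
    when any input band is nodata there or its quality is <= the cloud
    threshold (the same screen applied to plots); forest means FTY is
    coniferous or broadleaved.
    """
    h, w = stack.shape
    row1 = h if row1 is None else row1
    win = {name: stack.bands[name][row0:row1] for name in stack.bands}
    valid = np.ones((row1 - row0, w), dtype=bool)
    for name, arr in win.items():
        nd = stack.band_nodata(name)
        if nd is not None and np.isfinite(nd):
            valid &= arr != nd
        if np.issubdtype(arr.dtype, np.floating):
            valid &= np.isfinite(arr)
    valid &= win["QUALITY"] > quality_threshold
    fty = win["FTY"]
    forest = valid & ((fty == FTY_CONIFEROUS) | (fty == FTY_BROADLEAVED))

    cols = area.feature_columns()
    feats = np.full(((row1 - row0) * w, len(cols)), np.nan, dtype=np.float64)
    rows_idx, cols_idx = np.meshgrid(
        np.arange(row0, row1), np.arange(w), indexing="ij"
    )
    e, n = stack.transform.xy(rows_idx.ravel(), cols_idx.ravel())
    e1km, n1km = snap_to_1km_grid(e, n)
    for j, c in enumerate(cols):
        if c == "FTY":
            feats[:, j] = (fty.ravel() == FTY_CONIFEROUS).astype(np.float64)
        elif c == "E1KM":
            feats[:, j] = e1km
        elif c == "N1KM":
            feats[:, j] = n1km
        else:
            feats[:, j] = win[c].ravel().astype(np.float64)
    return feats, valid, forest


def predict_tile(
    model: KnnModel,
    stack: RasterStack,
    area: AreaConfig,
    block_rows: int | None = None,
) -> PredictionTile:
    """Predict all six output layers for a stack, windowed over row blocks.

    Non-forest and invalid pixels are skipped entirely (they can only ever
    be sentinel cells). ``block_rows=None`` processes the stack in one pass;
    any block size gives bit-identical results.
    """
    h, w = stack.shape
    block_rows = h if block_rows is None else block_rows
    layers = {v: np.full((h, w), np.nan, dtype=np.float32) for v in VARIABLES}
    valid = np.zeros((h, w), dtype=bool)
    forest = np.zeros((h, w), dtype=bool)
    for row0 in range(0, h, block_rows):
        row1 = min(row0 + block_rows, h)
        feats, v, f = pixel_features(stack, area, row0, row1)
        valid[row0:row1] = v
        forest[row0:row1] = f
        use = (v & f).ravel()
        if not use.any():
            continue
        Q = model.scaler.transform(feats[use])
        y_hat, s = model.predict_batch(Q)
        for r, (attr, stdev) in enumerate(RESPONSE_LAYERS):
            grid = layers[attr][row0:row1].ravel()
            grid[use] = y_hat[:, r]
            layers[attr][row0:row1] = grid.reshape(row1 - row0, w)
            grid = layers[stdev][row0:row1].ravel()
            grid[use] = s[:, r]
            layers[stdev][row0:row1] = grid.reshape(row1 - row0, w)
    return PredictionTile(layers=layers, valid_mask=valid, forest_mask=forest)


@dataclass
class RunConfig:
    """Run configuration: processing areas, kNN parameters, scaling, output."""

    areas: list[AreaConfig]
    knn: KnnConfig = field(default_factory=KnnConfig)
    scaling: str = "standardize"
    year: int = 2020
    epsg: int | None = 3035

    def __post_init__(self):
        seen: dict[str, str] = {}
        for a in self.areas:
            for t in a.member_tiles:
                if t in seen:
                    raise ConfigError(
                        f"tile {t} assigned to areas {seen[t]} and {a.area_id}"
                    )
                seen[t] = a.area_id

    def area(self, area_id: str) -> AreaConfig:
        for a in self.areas:
            if a.area_id == area_id:
                return a
        raise ConfigError(f"no processing area {area_id!r} in configuration")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration (areas / knn / scaling / output blocks)."""
    raw = yaml.safe_load(Path(path).read_text())
    areas = [
        AreaConfig(
            area_id=str(a["area_id"]),
            member_tiles=tuple(a.get("member_tiles", ())),
            contributing_countries=tuple(a.get("contributing_countries", ())),
            location_mode=a.get("location_mode", "both_axes"),
        )
        for a in raw.get("areas", [])
    ]
    knn_raw = raw.get("knn", {})
    return RunConfig(
        areas=areas,
        knn=KnnConfig(k=int(knn_raw.get("k", 7)), epsilon=float(knn_raw.get("epsilon", 1e-9))),
        scaling=raw.get("scaling", "standardize"),
        year=int(raw.get("year", 2020)),
        epsg=raw.get("epsg", 3035),
    )


def produce_maps(
    model: KnnModel,
    stack: RasterStack,
    area: AreaConfig,
    year: int,
    out_dir: str | Path,
    epsg: int | None = 3035,
    block_rows: int | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Predict one stack and write all six encoded output tiles plus a manifest.

    The tile label comes from the stack's lower-left corner; reduced-extent
    stacks yield small windows georeferenced inside their tile. Outputs are
    deterministic: re-running with identical inputs writes identical bytes.
    """
    tile = predict_tile(model, stack, area, block_rows=block_rows)
    xmin, ymin, _, _ = stack.transform.extent(stack.shape)
    label = tile_id_for(xmin, ymin)
    te, tn = (int(s) for s in label[1:].replace("_N", " ").split())
    paths = []
    for var in VARIABLES:
        values = np.nan_to_num(tile.layers[var], nan=0.0)
        enc = encode_uint16(values, tile.forest_mask, tile.valid_mask)
        spec = MapTileSpec(year=year, variable=var, tile_e=te, tile_n=tn)
        paths.append(
            write_map_tile(spec, enc, out_dir, transform=stack.transform, epsg=epsg)
        )
    manifest = {
        "year": year,
        "area_id": area.area_id,
        "tile": label,
        "epsg": epsg,
        "seed": seed,
        "knn": {"k": model.config.k, "epsilon": model.config.epsilon},
        "feature_columns": list(model.scaler.columns),
        "n_training_plots": int(len(model.X)),
        "counts": tile.counts(),
        "files": [p.name for p in paths],
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    out = Path(out_dir) / f"{year}_{label}_manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
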