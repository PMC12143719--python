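"""Synthetic forest scenes with a known ground truth.

The generator builds a spatially correlated landscape of above-ground
biomass (AGB), timber volume and conifer proportion, then renders the input
raster stack a mapping run consumes: seven spectral bands following a
saturating exponential response to AGB with additive Gaussian noise, a tree
cover density layer increasing in AGB, a forest-type layer derived from the
conifer proportion, a composite-quality layer with cloudy patches, and a
30 m canopy-loss-year layer. Finally it samples field plots whose responses
are the footprint-weighted ground truth, so every downstream step —
extraction, screening, splitting, kNN fitting, validation — can be tested
against known generative parameters.

Random fields are kernel-smoothed white noise rescaled to target moments;
AGB additionally passes through a lognormal transform so the landscape has
the heavy right tail real biomass distributions show (and so the highest
validation bins are populated). Spectral saturation (the exponential's decay
constant) reproduces the known optical-saturation mechanism that causes
regression-to-the-mean bias at the extremes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    FTY_BROADLEAVED,
    FTY_CONIFEROUS,
    FTY_NONFOREST,
    GridTransform,
    RasterStack,
)
from .signatures import FOOTPRINT_RADIUS, circle_footprint, weighted_mean

#: Saturating band response: value = a * exp(-agb / b) + c, reflectance x 1e4.
DEFAULT_BAND_MODEL = {
    "B2": (300.0, 120.0, 150.0),
    "B3": (500.0, 130.0, 250.0),
    "B4": (600.0, 110.0, 180.0),
    "B5": (900.0, 140.0, 400.0),
    "B8": (1200.0, 150.0, 2200.0),
    "B11": (1400.0, 130.0, 600.0),
    "B12": (900.0, 120.0, 300.0),
}


@dataclass
class SceneParams:
    """Generative parameters of a synthetic scene.

    Defaults describe a managed temperate/boreal landscape: lognormal AGB
    with mean 150 t/ha and sd 120 t/ha correlated over ~300 m, conifer
    proportion around 50 % over ~600 m, volume at 1.7 m³ per tonne of AGB,
    moderate sensor noise, 2 % cloud cover and 2 % recent canopy loss.
    """

    extent: float = 5_000.0  # m, square scene
    resolution: float = 10.0  # m
    origin: tuple[float, float] = (4_000_000.0, 2_800_000.0)  # lower-left, EPSG:3035
    agb_mean: float = 150.0  # t/ha
    agb_sd: float = 120.0  # t/ha
    agb_corr_length: float = 300.0  # m
    conifer_mean: float = 50.0  # %
    conifer_sd: float = 35.0  # %
    conifer_corr_length: float = 600.0  # m
    vol_ratio: float = 1.7  # m³ per t AGB
    band_model: dict = field(default_factory=lambda: dict(DEFAULT_BAND_MODEL))
    noise_sd: float = 50.0  # reflectance units, additive, per band
    tcd_scale: float = 60.0  # t/ha AGB at which canopy closes (1 - 1/e)
    forest_agb_threshold: float = 5.0  # t/ha, below -> non-forest
    cloud_fraction: float = 0.02
    loss_fraction: float = 0.02
    loss_year_range: tuple[int, int] = (2012, 2021)
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        n = int(round(self.extent / self.resolution))
        return n, n

    @property
    def transform(self) -> GridTransform:
        return GridTransform(
            origin_e=self.origin[0],
            origin_n=self.origin[1] + self.extent,
            pixel=self.resolution,
        )


@dataclass
class Landscape:
    """Ground-truth grids in physical units."""

    agb: np.ndarray  # t/ha
    vol: np.ndarray  # m³/ha
    dcp: np.ndarray  # % conifer share of AGB
    transform: GridTransform
    params: SceneParams


def _smooth_unit_field(rng: np.random.Generator, shape, corr_length, pixel) -> np.ndarray:
    """Kernel-smoothed white noise renormalised to zero mean, unit variance."""
    z = rng.standard_normal(shape)
    sigma_px = max(corr_length / pixel / 2.0, 1e-9)
    z = ndimage.gaussian_filter(z, sigma=sigma_px, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def generate_landscape(params: SceneParams) -> Landscape:
    """Generate the ground-truth AGB / volume / conifer-proportion grids.

    AGB is a lognormal transform of a smooth Gaussian field matched to the
    target mean and sd (exactly constant at the mean when sd = 0); the
    conifer proportion is a clipped Gaussian field; volume is proportional
    to AGB. Deterministic given the seed.
    """
    if params.extent <= 0:
        raise ValueError("extent must be positive")
    if params.agb_sd < 0 or params.conifer_sd < 0:
        raise ValueError("field standard deviations must be >= 0")
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    if params.agb_sd == 0:
        agb = np.full(shape, params.agb_mean)
    else:
        z = _smooth_unit_field(rng, shape, params.agb_corr_length, params.resolution)
        cv2 = (params.agb_sd / params.agb_mean) ** 2
        sigma = math.sqrt(math.log1p(cv2))
        mu = math.log(params.agb_mean) - 0.5 * sigma**2
        agb = np.exp(mu + sigma * z)
    if params.conifer_sd == 0:
        dcp = np.full(shape, params.conifer_mean)
    else:
        z = _smooth_unit_field(rng, shape, params.conifer_corr_length, params.resolution)
        dcp = np.clip(params.conifer_mean + params.conifer_sd * z, 0.0, 100.0)
    return Landscape(
        agb=agb, vol=params.vol_ratio * agb, dcp=dcp,
        transform=params.transform, params=params,
    )


def render_stack(landscape: Landscape, params: SceneParams | None = None) -> RasterStack:
    """Render the input raster stack consistent with a landscape.

    Bands follow the saturating response plus additive noise; TCD saturates
    in AGB; FTY is coniferous where the conifer share exceeds 50 %,
    broadleaved at or below, non-forest where AGB is under the forest
    threshold; the quality band drops to 2000 on cloudy patches covering
    ``cloud_fraction`` of the scene; canopy-loss years cover
    ``loss_fraction`` of the 30 m blocks.
    """
    p = params if params is not None else landscape.params
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 1]))
    shape = landscape.agb.shape
    bands: dict[str, np.ndarray] = {}
    for name, (a, b, c) in p.band_model.items():
        clean = a * np.exp(-landscape.agb / b) + c
        noise = rng.standard_normal(shape) * p.noise_sd if p.noise_sd > 0 else 0.0
        bands[name] = np.maximum(clean + noise, 0.0).astype(np.float32)

    bands["TCD"] = (100.0 * (1.0 - np.exp(-landscape.agb / p.tcd_scale))).astype(np.float32)

    fty = np.where(landscape.dcp > 50.0, FTY_CONIFEROUS, FTY_BROADLEAVED)
    fty = np.where(landscape.agb < p.forest_agb_threshold, FTY_NONFOREST, fty)
    bands["FTY"] = fty.astype(np.float32)

    quality = np.full(shape, 8000.0, dtype=np.float32)
    if p.cloud_fraction > 0:
        cloud_field = _smooth_unit_field(rng, shape, 8 * p.resolution, p.resolution)
        thresh = np.quantile(cloud_field, 1.0 - p.cloud_fraction)
        quality[cloud_field > thresh] = 2000.0
    bands["QUALITY"] = quality

    # 30 m canopy-loss grid covering the same extent
    n30 = int(math.ceil(p.extent / 30.0))
    gfc = np.zeros((n30, n30), dtype=np.float32)
    if p.loss_fraction > 0:
        lose = rng.random((n30, n30)) < p.loss_fraction
        lo, hi = p.loss_year_range
        gfc[lose] = rng.integers(lo, hi + 1, size=int(lose.sum()))
    gfc_transform = GridTransform(
        origin_e=p.origin[0], origin_n=p.origin[1] + n30 * 30.0, pixel=30.0
    )
    return RasterStack(
        bands=bands, transform=landscape.transform,
        gfc=gfc, gfc_transform=gfc_transform,
        nodata={},
    )


#: densest sensible sampling: one plot per 1000 m² triggers a warning
PLOT_DENSITY_CAP = 1.0 / 1000.0  # plots per m²


def sample_plots(
    landscape: Landscape,
    n: int,
    seed: int | None = None,
    country: str = "XX",
    year: int = 2020,
) -> pd.DataFrame:
    """Sample field plots uniformly over the scene interior.

    Plot centres stay at least one footprint radius inside the extent;
    responses are the area-weighted ground truth over the 100 m² footprint,
    via the same circle geometry used for signature extraction.
    """
    if n < 1:
        raise ValueError("need n >= 1 plots")
    p = landscape.params
    area = p.extent**2
    if n / area > PLOT_DENSITY_CAP:
        warnings.warn(
            f"{n} plots over {area:.0f} m² exceeds the density cap", stacklevel=2
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([p.seed, 2]) if seed is None else seed
    )
    pad = FOOTPRINT_RADIUS
    e0, n0 = p.origin
    e = rng.uniform(e0 + pad, e0 + p.extent - pad, size=n)
    nn = rng.uniform(n0 + pad, n0 + p.extent - pad, size=n)
    shape = landscape.agb.shape
    rows = []
    for i in range(n):
        fw = circle_footprint((e[i], nn[i]), landscape.transform, shape)
        agb = weighted_mean(landscape.agb, fw)
        rows.append({
            "plot_id": f"P{i:06d}",
            "easting": e[i],
            "northing": nn[i],
            "year": year,
            "country": country,
            "vol": weighted_mean(landscape.vol, fw),
            "agb": agb,
            "dcp": weighted_mean(landscape.dcp, fw),
        })
    return pd.DataFrame(rows)


def generate_scene(params: SceneParams, n_plots: int):
    """Convenience wrapper: landscape + rendered stack + plot table."""
    landscape = generate_landscape(params)
    stack = render_stack(landscape, params)
    plots = sample_plots(landscape, n_plots)
    return landscape, stack, plots
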