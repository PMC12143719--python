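import numpy as np
import pytest

from forestmap import (
    AreaConfig,
    SceneParams,
    build_feature_matrix,
    extract_signatures,
    fit,
    generate_scene,
    screen_plots,
    split_validation,
)
from forestmap.training import drop_nonforest, raw_feature_matrix


@pytest.fixture(scope="session")
def small_scene():
    """A 1 km² synthetic scene with 300 plots, clouds and canopy loss."""
    params = SceneParams(
        extent=1000.0, seed=11, cloud_fraction=0.05, loss_fraction=0.05,
        origin=(3_999_500.0, 2_799_500.0),  # straddles a 1 km grid line
    )
    landscape, stack, plots = generate_scene(params, 300)
    return params, landscape, stack, plots


@pytest.fixture(scope="session")
def screened_signatures(small_scene):
    _, _, stack, plots = small_scene
    sigs = extract_signatures(plots, stack)
    screened, counts = screen_plots(sigs)
    return screened, counts


@pytest.fixture(scope="session")
def fitted_pipeline(screened_signatures):
    """Mapping/validation split, training set and fitted model on the scene."""
    screened, _ = screened_signatures
    kept = screened[screened["screen_status"] == "kept"]
    mapping_set, validation_set = split_validation(kept)
    area = AreaConfig("test-area", location_mode="both_axes")
    ts = build_feature_matrix(mapping_set, area)
    model = fit(ts)
    return area, mapping_set, validation_set, ts, model


def validation_queries(model, validation_set, area):
    """Standardized feature rows for the forest validation plots."""
    vf = drop_nonforest(validation_set)
    return vf, model.scaler.transform(raw_feature_matrix(vf, area))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
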