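import numpy as np
import pytest

from berrytrace import (
    AcquisitionSpec,
    WavelengthAxis,
    default_origin_models,
    make_sample_library,
    render_scene,
)


@pytest.fixture(scope="session")
def instrument_axis() -> WavelengthAxis:
    """The 256-band 874-1734 nm reference instrument axis."""
    return WavelengthAxis.default_instrument()


@pytest.fixture(scope="session")
def origin_models():
    return default_origin_models()


@pytest.fixture(scope="session")
def small_axis() -> WavelengthAxis:
    """A short axis for fast tests: 40 bands over the fruit window."""
    return WavelengthAxis(np.linspace(950.0, 1650.0, 40))


@pytest.fixture(scope="session")
def noise_free_scene(origin_models):
    """Small rendered scene with zero noise: truth is exactly recoverable."""
    spec = AcquisitionSpec(n_rows=60, n_cols=120, n_bands=64)
    models = default_origin_models(noise_sd=0.0)
    return spec, render_scene(spec, models, n_objects_per_class=3, seed=11)


@pytest.fixture(scope="session")
def small_library(instrument_axis, origin_models):
    """120 object-wise sample spectra (30 per origin) at default noise."""
    return make_sample_library(origin_models, 30, instrument_axis, seed=7)
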