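import dataclasses

import numpy as np
import pytest

from biodose import (CellDensityParams, ImageGrid, OxyConversionParams,
                     PhantomSpec, RadiobioParams, RunConfig, generate_phantom)


@pytest.fixture(scope="session")
def oxy():
    return OxyConversionParams()


@pytest.fixture(scope="session")
def cd():
    return CellDensityParams()


@pytest.fixture(scope="session")
def rb():
    return RadiobioParams()


@pytest.fixture
def small_grid():
    return ImageGrid((10, 10, 10), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def clean_phantom():
    """Default phantom with the imaging corruption switched off."""
    spec = dataclasses.replace(PhantomSpec(), noise_cv=0.0, psf_sigma_mm=0.0)
    return generate_phantom(spec, seed=1)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom (5% multiplicative noise, 2 mm PSF), seed 1."""
    return generate_phantom(PhantomSpec(), seed=1)


@pytest.fixture(scope="session")
def pipeline_report():
    from biodose.pipeline import run_pipeline
    return run_pipeline(RunConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
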