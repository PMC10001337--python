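import numpy as np
import pytest

from utemt import (
    MTProtocol,
    MUSCLE,
    PhantomSpec,
    simulate_study,
)
from utemt.mt_model import mt_signal_grid
from utemt.roi_analysis import build_roi_series, run_variants


@pytest.fixture(scope="session")
def mt_protocol():
    return MTProtocol()


@pytest.fixture(scope="session")
def muscle_grid(mt_protocol):
    """Noise-free 15-point MT grid of the default muscle tissue."""
    return mt_signal_grid(MUSCLE.two_pool(), mt_protocol)


@pytest.fixture(scope="session")
def calibrated_grid(mt_protocol):
    """Pure-muscle grid with observed T1 = 1000 ms, calibrated so the fit
    at assumed T1 = 1000 ms returns MMF = 9%."""
    from utemt.synthetic_data import TissueParams

    tis = TissueParams(t1_ms=1000.0, mmf_percent=9.0, t2_free_ms=30.0)
    return mt_signal_grid(tis.two_pool(), mt_protocol)


@pytest.fixture(scope="session")
def default_study():
    """Noise-free default 96x96 muscle/fat phantom study."""
    return simulate_study(PhantomSpec())


@pytest.fixture(scope="session")
def roi_table(default_study):
    """Per-ROI measurement table over the seven expanding series."""
    series = build_roi_series(default_study.phantom.labels)
    return run_variants(series, default_study)


@pytest.fixture(scope="session")
def uniform_b1_study():
    """Phantom with a uniform B1 = 1 field (B1 correction is a no-op)."""
    return simulate_study(PhantomSpec(b1_field="uniform", b1_uniform_value=1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20230224)
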