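import numpy as np
import pytest

from tsimquant.extract import Chromatogram
from tsimquant.formula import MzWindow
from tsimquant.panel import builtin_panel
from tsimquant.simulate import AcquisitionParams, AnalyteSpec, simulate_run


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {t.name: t for t in panel}


@pytest.fixture(scope="session")
def fdump(panel_by_name):
    return panel_by_name["FdUMP"]


@pytest.fixture(scope="session")
def clean_fdump_run(fdump):
    """Noiseless, jitter-free single-analyte acquisition with its manifest."""
    analyte = AnalyteSpec(compound=fdump, concentration=1.0, rt_jitter_sd=0.0)
    acq = AcquisitionParams(mz_error_ppm_sd=0.0)
    return simulate_run([analyte], acquisition=acq, seed=11, sample_id="clean_fdump")


def gaussian_chromatogram(amplitude, sigma, apex=1.5, dt=None, span=6.0, window=None):
    """Sampled noiseless Gaussian peak for integration tests."""
    dt = dt if dt is not None else sigma / 5.0
    rt = np.arange(apex - span * sigma, apex + span * sigma + dt / 2, dt)
    y = amplitude * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)
    return Chromatogram(
        rt=rt, intensity=y, window=window or MzWindow(99.0, 101.0), ms_level=1
    )
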