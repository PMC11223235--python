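import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fodspec.calibration import fit_calibration, find_zero_crossing
from fodspec.spectra import DerivParams, differentiate_with
from fodspec.synth import (
    NoiseModel,
    default_asc_model,
    default_grid,
    default_nic_model,
    gen_calibration_set,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


QUIET = NoiseModel(additive_sd=0.0)

#: derivative settings used by the pipeline for noisy spectra
PIPELINE_DERIV = DerivParams(method="savitzky_golay", window=31, polyorder=2)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def asc_model():
    return default_asc_model()


@pytest.fixture(scope="session")
def nic_model():
    return default_nic_model()


@pytest.fixture(scope="session")
def models(asc_model, nic_model):
    return (asc_model, nic_model)


def build_curves(models, grid, noise=QUIET, deriv=PIPELINE_DERIV, levels=None):
    """Calibration curves for both analytes from a generated standard series."""
    spectra = gen_calibration_set(levels or [float(c) for c in range(2, 25, 2)],
                                  models, noise, grid)
    amps = {"ASC": [], "NIC": []}
    wavelengths = {"ASC": 261.0, "NIC": 243.0}
    for sp in spectra:
        d = differentiate_with(sp, deriv, order=1)
        for analyte, wl in wavelengths.items():
            conc = sp.meta[f"true_conc_{analyte.lower()}_ug_ml"]
            amps[analyte].append((conc, d.values[d.index_of(wl)]))
    return {
        analyte: fit_calibration(pairs, analyte, wavelengths[analyte])
        for analyte, pairs in amps.items()
    }


@pytest.fixture(scope="session")
def quiet_curves(models, grid):
    """Noise-free calibration curves at the 261/243 nm crossing pair."""
    return build_curves(models, grid)
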