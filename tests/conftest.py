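import pytest

from triohap.correction import CorrectionTable
from triohap.model import (
    calibration_mean_shift_table,
    load_panel,
    load_shift_calibration,
)
from triohap.synthetic_data import PopulationModel, ShiftModelParams


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def calibration():
    return load_shift_calibration()


@pytest.fixture(scope="session")
def mean_shift_table():
    """Per-dye (R, mean shift) pairs from the bundled calibration."""
    return calibration_mean_shift_table()


@pytest.fixture(scope="session")
def calibration_correction_table(mean_shift_table):
    """The bundled mean-coefficient table as a CorrectionTable."""
    return CorrectionTable.from_mean_shift_table(mean_shift_table)


@pytest.fixture()
def noise_free_params(mean_shift_table):
    return ShiftModelParams(
        mean_shift=mean_shift_table,
        sigma_run=0.0,
        sigma_eps={d: 0.0 for d in mean_shift_table},
        seed=0,
    )


def make_population(panel, n_families=100, risk_freq=0.0, seed=0, freqs=None):
    if freqs is None:
        freqs = {
            name: {r: 1.0 / len(lad.rungs) for r in lad.rungs}
            for name, lad in panel.ladders.items()
        }
    return PopulationModel(
        allele_freqs=freqs, risk_freq=risk_freq, n_families=n_families, seed=seed
    )


@pytest.fixture()
def population(panel):
    return make_population(panel)
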