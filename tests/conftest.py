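import warnings

import pytest

from emodyn.params import reference_expression_coeffs, reference_params
from emodyn.synth import ReadingStudyDesign


@pytest.fixture(scope="session")
def params():
    """Reference point estimates shipped with the package."""
    return reference_params()


@pytest.fixture(scope="session")
def expr_coeffs():
    return reference_expression_coeffs()


@pytest.fixture
def noise_free_design():
    """Small reading study with every noise source switched off."""
    return ReadingStudyDesign(
        n_participants=20,
        noise=(0.0, 0.0),
        report_noise_sd=0.0,
        intention_noise_sd=0.0,
        quantize=False,
        seed=7,
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="skipping subset")
        yield
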