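import pytest

from pmhrank import default_questionnaire, reference_fixtures, sample_catalogue
from pmhrank.utility import UtilityParams


@pytest.fixture(scope="session")
def config():
    return default_questionnaire()


@pytest.fixture(scope="session")
def fx():
    """The published worked-example tables."""
    return reference_fixtures()


@pytest.fixture(scope="session")
def catalogue7():
    """The 7-activity worked-example catalogue."""
    return sample_catalogue()


@pytest.fixture(scope="session")
def params():
    """Deployed reward-penalty calibration (k_pos=4, k_neg=3, threshold 2.5)."""
    return UtilityParams()
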