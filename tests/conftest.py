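import pytest

from roughdx.model import DiabetesRuleModel
from roughdx.synthetic import generate_dmis


@pytest.fixture(scope="session")
def dmis():
    """Default synthetic cohort, fixed seed."""
    return generate_dmis(seed=1)


@pytest.fixture(scope="session")
def fitted(dmis):
    """Fitted model on the default synthetic cohort."""
    return DiabetesRuleModel(dmis).fit()
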