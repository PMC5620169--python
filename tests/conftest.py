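import matplotlib

matplotlib.use("Agg")

import pytest

from cardiomap import delta_delta_ct, simulate_study


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared by read-only tests."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def expression(study):
    return delta_delta_ct(study.ct)
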