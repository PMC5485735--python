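import numpy as np
import pytest

from nmrprofiler import default_region_table, default_template, generate_profiles


@pytest.fixture(scope="session")
def rt():
    return default_region_table()


@pytest.fixture(scope="session")
def tpl(rt):
    return default_template(rt)


@pytest.fixture(scope="session")
def null_tpl(tpl):
    return tpl.as_null()


@pytest.fixture(scope="session")
def dataset(tpl):
    """One 7 vs 7 default-template dataset, fixed seed."""
    return generate_profiles(tpl, 7, 7, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
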