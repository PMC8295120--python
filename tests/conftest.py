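import pytest

from logpka import ProtonParameters, ThermoConditions
from logpka.datasets import load_sampl7_logp, load_sampl7_pka


@pytest.fixture(scope="session")
def cond():
    return ThermoConditions()


@pytest.fixture(scope="session")
def proton():
    return ProtonParameters()


@pytest.fixture(scope="session")
def logp_benchmark():
    """The 22-compound SAMPL7 log P table (calculated vs experimental)."""
    return load_sampl7_logp()


@pytest.fixture(scope="session")
def pka_benchmark():
    """The SAMPL7 pKa table, with the two censored entries auto-excluded."""
    return load_sampl7_pka()
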