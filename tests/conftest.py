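import pytest

from mksweep import linkage as lk
from mksweep import model as mdl
from mksweep import synth


@pytest.fixture(scope="session")
def panel():
    return synth.make_panel(seed=101)


@pytest.fixture(scope="session")
def sweep_pair(panel):
    """A pre-sweep and near-equilibrium post-sweep sample of 48 diploids."""
    samples, truth = synth.simulate_sweep_samples(
        panel, sample_times=(0, 50), n=48, seed=202
    )
    return samples[0], samples[1], truth


@pytest.fixture(scope="session")
def male_family(panel):
    return synth.simulate_cross_family(lk.MALE_INFORMATIVE, panel=panel, seed=303)


@pytest.fixture(scope="session")
def female_family(panel):
    return synth.simulate_cross_family(lk.FEMALE_INFORMATIVE, panel=panel, seed=404)


@pytest.fixture(scope="session")
def default_params():
    return mdl.ModelParams()
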