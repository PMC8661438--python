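import numpy as np
import pytest

from fishor.synth import ImplantPlan, implant_genome, make_reference_set


@pytest.fixture(scope="session")
def refs():
    """Small labeled reference set: 3 families x 2 members + 7 decoys."""
    return make_reference_set(["delta", "eta", "beta"], 2, protein_length=310,
                              divergence=0.05, seed=9)


@pytest.fixture(scope="session")
def small_genome(refs):
    """One genome with all four implant classes at divergence 0.05."""
    plan = ImplantPlan(n_functional=3, n_pseudo=2, n_truncated=1, n_edge=1,
                       scaffold_sizes=(30_000, 20_000), divergence=0.05)
    return implant_genome(refs, plan, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
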