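import numpy as np
import pytest
from hypothesis import settings

from ecpred.reaction_model import BondChangeVector, ReactionEntry, Species
from ecpred.synthetic_data import GeneratorConfig, generate_dataset

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("suite")


def make_entry(entry_id="E1", ec="3.4.21.1", overall=None, mechanism=None,
               species=None):
    """Hand-build a small entry; defaults model an amide hydrolysis."""
    overall = BondChangeVector.from_strings(
        overall if overall is not None
        else {"C.N_1.0": 1, "C.O_0.1": 1, "H.N_0.1": 1})
    if mechanism is None:
        steps = [overall]
    else:
        steps = [BondChangeVector.from_strings(s) for s in mechanism]
    if species is None:
        species = [
            Species("substrate_1", "C4H9NO3", "substrate"),
            Species("water", "H2O", "substrate"),
            Species("product_1", "C2H5NO2", "product"),
            Species("product_2", "C2H6O2", "product"),
        ]
    return ReactionEntry(entry_id=entry_id, ec=ec, species=species,
                         overall_changes=overall, mechanism=steps)


@pytest.fixture
def amide_entry():
    return make_entry().validate()


@pytest.fixture(scope="session")
def dataset():
    """One medium synthetic dataset shared by read-only tests."""
    return generate_dataset(GeneratorConfig(n_entries=120, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_step(rng, n_tokens=(1, 4)):
    """A random bond-change vector drawn from the generator's noise alphabet."""
    from ecpred.synthetic_data import NOISE_ALPHABET
    k = int(rng.integers(*n_tokens))
    toks = {}
    for _ in range(k):
        t = NOISE_ALPHABET[int(rng.integers(len(NOISE_ALPHABET)))]
        toks[t] = toks.get(t, 0) + 1
    return BondChangeVector(toks)
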