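import numpy as np
import pytest

import rbpstruct as rb

NT = np.array(list("ACGU"))


def random_rna(rng, length):
    return "".join(NT[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def basic_em():
    return rb.EnergyModel()


@pytest.fixture(scope="session")
def turner_em():
    return rb.EnergyModel(backend="turner")


@pytest.fixture(scope="session")
def small_probe_set(turner_em):
    """60 random probes with turner-backend context profiles (shared across
    tests to amortize folding)."""
    probes = rb.random_probes(60, seed=11)
    seqs = [p.seq for p in probes]
    profiles = rb.profiles_for_probes(seqs, turner_em)
    return seqs, profiles


@pytest.fixture(scope="session")
def planted_dataset(small_probe_set):
    """Noise-free intensities from the default planted model."""
    seqs, profiles = small_probe_set
    planted = rb.default_planted_model()
    y = np.array([rb.score_probe(planted, s, p) for s, p in zip(seqs, profiles)])
    return seqs, profiles, y, planted
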