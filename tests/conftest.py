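"""Shared fixtures: small synthetic worlds and deterministic RNGs."""

import numpy as np
import pytest

from avimark import synthdata


@pytest.fixture(scope="session")
def backbone_spec():
    """Conserved-backbone world: 6 hosts, one planted unique window each."""
    return synthdata.default_spec(seed=11)


@pytest.fixture(scope="session")
def unrelated_spec():
    """World where hosts share no usable backbone (whole sequence is a
    host-signature variable region), so E-value-only read verification is
    discriminative."""
    return synthdata.SynthSpec(
        seed=7, n_hosts=4, backbone_length=400,
        variable_regions=((0, 400, 1.0),),
        planted_unique=(), reads_per_host=25)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(rng, seq, rate):
    """Substitute bases at the given per-base rate (to a different base)."""
    out = list(seq)
    bases = "ACGT"
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = bases[(bases.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)
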