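"""Shared fixtures: synthetic organisms generated once per session."""

import numpy as np
import pytest

from genesimplex import (build_vocabulary, embed_records, make_profile,
                         perturb_profile, sample_genome)
from genesimplex.synthetic import LengthLaw, OrganismProfile, _build_transition

BASE_SEED = 17


@pytest.fixture(scope="session")
def nt_vocab():
    return build_vocabulary("nucleotide")


@pytest.fixture(scope="session")
def codon_vocab():
    return build_vocabulary("codon")


@pytest.fixture(scope="session")
def pair_vocab():
    return build_vocabulary("codon_pair")


@pytest.fixture(scope="session")
def profile_a():
    """Reference organism: moderately biased codon usage with
    adjacent-codon correlation."""
    return make_profile(BASE_SEED, skew=0.3, correlation=0.3, label="orgA")


@pytest.fixture(scope="session")
def genome_a(profile_a):
    """1000 genes from the reference organism."""
    return sample_genome(profile_a, 1000, BASE_SEED + 1)


@pytest.fixture(scope="session")
def matrix_a(genome_a, codon_vocab):
    return embed_records(genome_a, codon_vocab, "orgA")


@pytest.fixture(scope="session")
def matrix_a_nt(genome_a, nt_vocab):
    return embed_records(genome_a, nt_vocab, "orgA")


@pytest.fixture(scope="session")
def matrix_a_pair(genome_a, pair_vocab):
    return embed_records(genome_a, pair_vocab, "orgA")


@pytest.fixture(scope="session")
def profile_b(profile_a):
    """Strongly diverged sibling of the reference organism."""
    return perturb_profile(profile_a, 1.0, BASE_SEED + 2, label="orgB")


@pytest.fixture(scope="session")
def matrix_b(profile_b, codon_vocab):
    recs = sample_genome(profile_b, 500, BASE_SEED + 3)
    return embed_records(recs, codon_vocab, "orgB")


def disjoint_support_profiles():
    """Two organisms whose codon usage has disjoint support — linearly
    separable by construction."""
    rng = np.random.default_rng(BASE_SEED + 4)
    p1 = np.zeros(61)
    p1[:30] = 1.0 / 30
    p2 = np.zeros(61)
    p2[30:] = 1.0 / 31
    law = LengthLaw()
    a = OrganismProfile("supportA", p1, _build_transition(p1, 0.0, rng),
                        law, 1)
    b = OrganismProfile("supportB", p2, _build_transition(p2, 0.0, rng),
                        law, 2)
    return a, b
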