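import numpy as np
import pytest

from superbarcode.seqio import AlignmentRecord, LabeledAlignment


def make_alignment(seqs, species=None, ids=None, name="test"):
    n = len(seqs)
    ids = ids or [f"a{i + 1}" for i in range(n)]
    species = species or [f"sp{i + 1}" for i in range(n)]
    return LabeledAlignment(
        [AlignmentRecord(a, s, q) for a, s, q in zip(ids, species, seqs)], name=name
    )


@pytest.fixture
def aln_three():
    """The 3-sequence worked example: Pi = 1/3 under complete deletion."""
    return make_alignment(["AAAA", "AAAT", "AATT"])


@pytest.fixture
def aln_four():
    """4-sequence fixture: 2 variable sites, both parsimony-informative."""
    return make_alignment(["AAAA", "AAAT", "AATT", "AATA"])


def random_alignment(rng, n, length, p_gap=0.05, p_n=0.02, n_species=None):
    """Random alignment with gaps and Ns for brute-force comparisons."""
    bases = np.array(list("ACGT-N"))
    probs = [(1 - p_gap - p_n) / 4] * 4 + [p_gap, p_n]
    seqs = ["".join(rng.choice(bases, size=length, p=probs)) for _ in range(n)]
    n_species = n_species or n
    species = [f"sp{rng.integers(n_species) + 1:02d}" for _ in range(n)]
    return make_alignment(seqs, species=species)


@pytest.fixture
def small_community():
    """A fast 6-species simulated community with a clear barcoding gap."""
    from superbarcode.synthdata import SimulationParams, simulate_community

    params = SimulationParams(
        seed=7,
        n_species=6,
        individuals_per_species=3,
        alignment_length=4000,
        interspecific_scale=0.02,
        intraspecific_scale=0.002,
        indel_rate=0.002,
        indel_length_mean=4.0,
        min_species_stem=0.004,
    )
    return simulate_community(params)
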