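import numpy as np
import pytest

from mirpopgen.seqdata import Haplotype, LocusAlignment


def make_alignment(seqs, locus_id="locus", outgroup=None, pops=None):
    """Build a LocusAlignment from bare sequence strings."""
    pops = pops or ["P1"] * len(seqs)
    haps = tuple(
        Haplotype(f"s{i + 1}", p, s) for i, (s, p) in enumerate(zip(seqs, pops))
    )
    return LocusAlignment(locus_id, haps, outgroup)


def random_alignment(rng, n=None, L=None, gap_prob=0.0):
    """Random alignment for brute-force oracle comparisons."""
    n = n or int(rng.integers(2, 11))
    L = L or int(rng.integers(1, 51))
    alphabet = np.array(list("ACGT"))
    mat = alphabet[rng.integers(4, size=(n, L))]
    if gap_prob:
        mat[rng.random((n, L)) < gap_prob] = "-"
    # ensure no all-gap sequence
    for i in range(n):
        if (mat[i] == "-").all():
            mat[i, 0] = "A"
    return make_alignment(["".join(row) for row in mat])


@pytest.fixture
def aln_factory():
    return make_alignment


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 12-locus synthetic dataset on disk, shared across pipeline tests."""
    from mirpopgen.synthetic_data import EventSpec, SyntheticConfig, generate_dataset

    out = tmp_path_factory.mktemp("dataset")
    cfg = SyntheticConfig(
        seed=42,
        num_loci=12,
        injected_events=(
            EventSpec(locus=3, kind="deletion", population="ON", frequency=2 / 9),
            EventSpec(locus=5, kind="seed_snp", population="OH", frequency=0.3),
        ),
    )
    manifest = generate_dataset(cfg, out)
    return out, cfg, manifest
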