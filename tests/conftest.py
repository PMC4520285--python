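import numpy as np
import pytest

from snepscan import synthetic as syn


@pytest.fixture(scope="session")
def small_genomes():
    return syn.generate_genomes(
        7, 40_000, n_strains=2, snp_rate=0.005, indel_rate=0.0002, indel_size_max=10
    )


@pytest.fixture(scope="session")
def small_landscape(small_genomes):
    return syn.generate_landscape(
        8,
        small_genomes,
        fuzzy_fraction=0.1,
        n_shifted=5,
        shift_range=(30, 30),
        n_evicted=3,
    )


@pytest.fixture(scope="session")
def small_genes(small_genomes):
    return syn.make_genes(9, 40_000, 12)


@pytest.fixture(scope="session")
def small_readset(small_landscape, small_genes):
    return syn.simulate_reads(
        10,
        small_landscape,
        ["H3K4me3", "H3K14ac"],
        80_000,
        n_replicates=3,
        genes=small_genes,
        planted_sneps=[("nuc00020", "H3K4me3", 2.5)],
    )


def brute_force_mapping(length: int, variants) -> dict[int, int]:
    """Per-base alignment walk: source position -> target position.

    Deleted source bases map to the left flank of the deletion, matching
    the translation convention under test (computed independently here by
    walking aligned columns one base at a time).
    """
    by_offset = {v.offset: v for v in variants if v.type != "snp"}
    mapping = {}
    s, t = 0, 0
    while s < length:
        v = by_offset.get(s)
        if v is not None and v.type == "del":
            for i in range(v.size):
                mapping[s + i] = t - 1
            s += v.size
            continue
        if v is not None and v.type == "ins":
            t += v.size
        mapping[s] = t
        s += 1
        t += 1
    return mapping
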