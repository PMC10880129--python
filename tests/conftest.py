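import numpy as np
import pytest

from dayflower.datatypes import MISSING, GenotypeMatrix, PopulationMeta


def random_matrix(rng, n_ind=12, n_loci=8, n_pops=3, missing_rate=0.2):
    """Random genotype matrix for round-trip / invariance tests."""
    calls = rng.integers(0, 3, size=(n_ind, n_loci)).astype(np.int8)
    calls[rng.random((n_ind, n_loci)) < missing_rate] = MISSING
    inds = [f"ind{i}" for i in range(n_ind)]
    pop_of = {ind: f"pop{i % n_pops}" for i, ind in enumerate(inds)}
    return GenotypeMatrix(
        individual_ids=inds,
        locus_ids=[f"L{j}" for j in range(n_loci)],
        calls=calls,
        pop_of=pop_of,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_filter_matrix():
    """10 individuals x 6 loci where each filter removes exactly one target.

    - ind10 is 50% missing (> 40%) -> removed by the sample filter.
    - L1 is then called in 6/9 individuals (0.667 < 0.8) -> coverage.
    - L2 and L3 share a locus-group tag -> L3 removed by single-SNP.
    - L4 is monomorphic (maf 0 < 0.01) -> maf.
    - L5 is heterozygous in every call (H_obs = 1 > 0.95) -> obs-het.
    - L2 and L6 survive.
    """
    M = MISSING
    #        L1 L2 L3 L4 L5 L6
    rows = [
        [0,  1,  1,  0,  1,  0],
        [1,  0,  0,  0,  1,  1],
        [2,  1,  1,  0,  1,  2],
        [M,  2,  2,  0,  1,  0],
        [M,  0,  0,  0,  1,  1],
        [M,  1,  1,  0,  1,  2],
        [0,  2,  2,  0,  1,  0],
        [1,  0,  0,  0,  1,  1],
        [2,  1,  1,  0,  1,  2],
        [M,  M,  M,  0,  1,  0],   # ind10: 3/6 = 50% missing
    ]
    inds = [f"ind{i + 1}" for i in range(10)]
    pop_of = {ind: "popA" if i < 5 else "popB" for i, ind in enumerate(inds)}
    return GenotypeMatrix(
        individual_ids=inds,
        locus_ids=["L1", "L2", "L3", "L4", "L5", "L6"],
        calls=np.array(rows, dtype=np.int8),
        pop_of=pop_of,
        locus_groups={"L2": "tag1", "L3": "tag1"},
    )


@pytest.fixture
def square_meta():
    """Four sites on a small square with full land-cover tables."""
    lc = lambda dev, ag, fo, gr: {
        r: {"developed": dev * r, "agricultural": ag * r, "forest": fo * r,
            "grassland": gr * r}
        for r in (250, 500, 1000)
    }
    return {
        "p1": PopulationMeta("p1", "RA", 35.00, 135.00, lc(10, 70, 15, 5)),
        "p2": PopulationMeta("p2", "UA", 35.00, 135.10, lc(50, 35, 10, 5)),
        "p3": PopulationMeta("p3", "UP", 35.10, 135.00, lc(55, 5, 25, 15)),
        "p4": PopulationMeta("p4", "UR", 35.10, 135.10, lc(80, 5, 5, 10)),
        "p5": PopulationMeta("p5", "RA", 35.05, 135.05, lc(5, 80, 10, 5)),
        "p6": PopulationMeta("p6", "UR", 35.02, 135.08, lc(70, 10, 10, 10)),
    }
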