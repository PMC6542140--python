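import numpy as np
import pytest

from fireant_demog.io_formats import MISSING, GenotypeMatrix, Locus


def make_random_matrix(
    rng,
    n_samples: int = 12,
    n_loci: int = 40,
    pops=("A", "B"),
    missing_rate: float = 0.12,
    with_depth: bool = True,
    n_contigs: int = 2,
) -> GenotypeMatrix:
    """Random but valid genotype matrix exercising missingness and depth."""
    calls = rng.integers(0, 3, (n_samples, n_loci)).astype(np.int8)
    calls[rng.random((n_samples, n_loci)) < missing_rate] = MISSING
    depth = (
        rng.poisson(6, (n_samples, n_loci)).astype(np.int32) if with_depth else None
    )
    loci = []
    per = -(-n_loci // n_contigs)
    j = 0
    for c in range(n_contigs):
        pos = 0
        for _ in range(per):
            if j >= n_loci:
                break
            pos += int(rng.integers(500, 9000))
            loci.append(Locus(f"c{c:02d}", pos, "A", "C"))
            j += 1
    pop_labels = [pops[i % len(pops)] for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=[f"s{i:02d}" for i in range(n_samples)],
        pop_labels=pop_labels,
        loci=loci,
        calls=calls,
        depth=depth,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def random_matrix(rng):
    return make_random_matrix(rng)


def assert_matrices_equal(a: GenotypeMatrix, b: GenotypeMatrix, check_depth=True):
    assert a.sample_ids == b.sample_ids
    assert a.pop_labels == b.pop_labels
    assert a.loci == b.loci
    np.testing.assert_array_equal(a.calls, b.calls)
    if check_depth:
        if a.depth is None:
            assert b.depth is None
        else:
            np.testing.assert_array_equal(a.depth, b.depth)
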