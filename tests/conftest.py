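import numpy as np
import pytest

from gsca.panel import HaplotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_panel():
    """K=3 haplotypes over 4 SNPs; Q = (0.5, 0.25, 0.25)."""
    alleles = np.array(
        [
            [0, 0, 1, 0],
            [1, 0, 0, 1],
            [1, 1, 1, 0],
        ],
        dtype=np.int8,
    )
    return HaplotypePanel(
        set_id="gs_test",
        alleles=alleles,
        Q=np.array([0.5, 0.25, 0.25]),
        line_to_hap={"l0": 0, "l1": 0, "l2": 1, "l3": 2},
    )


def random_panel(rng, K=3, m=4):
    """A random panel with every SNP polymorphic and distinct haplotypes."""
    while True:
        alleles = (rng.random((K, m)) < 0.5).astype(np.int8)
        poly = all(0 < alleles[:, j].sum() < K for j in range(m))
        distinct = len({row.tobytes() for row in alleles}) == K
        if poly and distinct:
            break
    q = rng.random(K) + 0.2
    return HaplotypePanel("gs_rand", alleles, q / q.sum())
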