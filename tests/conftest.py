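import numpy as np
import pandas as pd
import pytest

from boamap import (
    PhasedGenotypes,
    ReferenceLabels,
    SimConfig,
    SnpMap,
    simulate_study,
)


def make_map(positions, chrom=None, prefix="s"):
    n = len(positions)
    chrom = chrom or ["1"] * n
    return SnpMap(
        snp_id=np.array([f"{prefix}{i}" for i in range(n)], dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(positions, dtype=np.int64),
        ref_allele=np.array(["A"] * n, dtype=object),
        alt_allele=np.array(["B"] * n, dtype=object),
    )


@pytest.fixture
def tiny_map():
    return make_map([1, 50_000, 100_000, 100_001, 150_000, 250_000])


@pytest.fixture
def tiny_genotypes(tiny_map):
    rng = np.random.default_rng(7)
    alleles = rng.integers(0, 2, size=(4, tiny_map.n_snp, 2)).astype(np.uint8)
    return PhasedGenotypes([f"a{i}" for i in range(4)], tiny_map, alleles)


@pytest.fixture
def tiny_labels():
    return ReferenceLabels(
        pd.DataFrame(
            {
                "animal_id": ["a0", "a1", "a2", "a3"],
                "subspecies": ["indicus", "indicus", "taurus", "taurus"],
                "breed": ["b1", "b1", "b2", "b2"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but fully structured simulated study shared across tests."""
    cfg = SimConfig(
        n_snp=400,
        n_ref_bi=50,
        n_ref_bt=50,
        n_target_per_breed=60,
        n_qtl=5,
        seed=11,
    )
    return simulate_study(cfg)
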