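import numpy as np
import pytest

from popgenpipe.genotypes import GenotypeMatrix, snp_table
from popgenpipe import synthetic_data as sd


def make_panel(dosage, pops=None, chrom=None, pos=None, alleles=None, ids=None):
    """Small hand-built GenotypeMatrix for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pops is None:
        pops = ["P1"] * n
    if chrom is None:
        chrom = [1] * m
    if pos is None:
        pos = list(range(1, m + 1))
    if alleles is None:
        alleles = [("A", "G")] * m
    if ids is None:
        ids = [f"s{j}" for j in range(m)]
    snps = snp_table(ids, chrom, pos, [a for a, _ in alleles], [b for _, b in alleles])
    samples = np.array([f"ind{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(samples, np.array(pops, dtype=object), snps, dosage)


@pytest.fixture
def tiny_panel():
    # 2 samples x 3 SNPs used by the PED/MAP round-trip checks
    return make_panel(
        [[0, 1, 2], [2, 1, 0]],
        pops=["FAM1", "FAM2"],
        chrom=[1, 1, 2],
        pos=[100, 200, 150],
    )


@pytest.fixture(scope="session")
def sim_two_pop():
    """Two moderately diverged populations, deterministic."""
    cfg = sd.SimConfig(
        n_chromosomes=4,
        snps_per_chromosome=250,
        chromosome_length_bp=50_000_000,
        populations=[
            sd.PopulationSpec("A", 20, [(10, 80)]),
            sd.PopulationSpec("B", 20, [(10, 80)]),
        ],
        missing_rate=0.02,
        seed=42,
    )
    return sd.simulate_panel(cfg)


@pytest.fixture(scope="session")
def sim_panel_qcd(sim_two_pop):
    from popgenpipe.genotype_io import QCConfig, apply_qc

    g, _ = sim_two_pop
    g2, _ = apply_qc(g, QCConfig(n_autosomes=26))
    return g2


@pytest.fixture(scope="session")
def shaped_panel():
    """Reduced-size five-population integration fixture (shared)."""
    return sd.five_breed_panel(seed=7, snps_per_chromosome=300)
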