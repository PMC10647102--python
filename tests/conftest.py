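import numpy as np
import pytest

import admixburden as ab

TINY_MAP = [("chr1", 1_000_000, 0.01)]


def make_variant(pos=500_000, f_afr=0.01, f_eur=0.01, or_assumed=1.0,
                 rsid="rsT", gene="GENE", chrom="chr1", direction="risk"):
    return ab.VariantSpec(chrom=chrom, pos=pos, ref="A", alt="G", rsid=rsid,
                          gene=gene, f_afr=f_afr, f_eur=f_eur,
                          or_assumed=or_assumed, direction=direction)


def make_cohort(gts, variants, phenotypes=None):
    """Cohort from a nested genotype list: gts[sample][variant] = (a, b)."""
    alleles = np.array(gts, dtype=np.int8)
    samples = [f"S{i}" for i in range(alleles.shape[0])]
    return ab.PhasedCohort(samples, variants, alleles, phenotypes)


def uniform_tracts(samples, chrom_lengths, ancestry="AFR"):
    """Single-tract-per-haplotype TractSet with one ancestry everywhere."""
    from admixburden.cohort import ANCESTRY_CODES

    code = ANCESTRY_CODES[ancestry]
    data = {}
    for chrom, L in chrom_lengths.items():
        data[chrom] = [
            (np.array([0, L], dtype=np.int64), np.array([code], dtype=np.int8))
            for _ in range(2 * len(samples))
        ]
    return ab.TractSet(samples, chrom_lengths, data)


@pytest.fixture
def tiny_map():
    return list(TINY_MAP)


@pytest.fixture(scope="session")
def cd_table():
    return ab.load_cd_variant_table()


@pytest.fixture(scope="session")
def ep_table():
    return ab.load_ep_variant_table()


@pytest.fixture(scope="session")
def demo_sim():
    """A small but structured simulated cohort shared by read-only tests."""
    cfg = ab.SimulationConfig(
        n_cases=60, n_controls=240, alpha=0.8, generations=12, prevalence=0.01,
        chrom_map=[("chr1", 50_000_000, 0.5), ("chr2", 30_000_000, 0.3)], seed=42)
    variants = [
        make_variant(pos=10_000_000, f_afr=0.01, f_eur=0.05, or_assumed=2.0, rsid="rsA", gene="G1"),
        make_variant(pos=25_000_000, f_afr=0.0, f_eur=0.04, or_assumed=1.5, rsid="rsB", gene="G2"),
        make_variant(pos=5_000_000, chrom="chr2", f_afr=0.05, f_eur=0.05, or_assumed=1.0,
                     rsid="rsC", gene="G3"),
        make_variant(pos=20_000_000, chrom="chr2", f_afr=0.02, f_eur=0.1, or_assumed=0.7,
                     rsid="rsD", gene="G4", direction="protective"),
    ]
    cohort, tracts = ab.simulate_cohort(cfg, variants, pool_size=12_000)
    return cfg, variants, cohort, tracts
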