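"""PRS scoring/correlations and adjusted CDS nucleotide diversity."""

import itertools

import numpy as np
import pandas as pd
import pytest

import admixburden as ab
from admixburden.diversity import replicate_summary
from admixburden.errors import ConfigError, DegenerateInputError

from conftest import make_cohort, make_variant


# -- PRS ---------------------------------------------------------------------

def prs_cohort():
    variants = [make_variant(pos=10, rsid="rs1"), make_variant(pos=20, rsid="rs2")]
    gts = [[(0, 1), (1, 1)], [(0, 0), (0, 1)], [(1, 1), (0, 0)]]
    return make_cohort(gts, variants)


def test_prs_single_variant_weight_scales_genotype():
    cohort = prs_cohort()
    w = ab.WeightTable({"rs1": 0.5}, label="single")
    res = ab.prs_score(cohort, w)
    assert res.scores.tolist() == [0.5, 0.0, 1.0]
    assert res.n_resolved == 1


def test_prs_zero_weights_zero_scores():
    cohort = prs_cohort()
    res = ab.prs_score(cohort, ab.WeightTable({"rs1": 0.0, "rs2": 0.0}, label="null"))
    assert np.allclose(res.scores, 0.0)


def test_prs_is_linear_in_weights():
    cohort = prs_cohort()
    w1 = ab.WeightTable({"rs1": 0.3, "rs2": -0.2}, label="w1")
    w2 = ab.WeightTable({"rs1": 0.1, "rs2": 0.4}, label="w2")
    wsum = ab.WeightTable({"rs1": 0.4, "rs2": 0.2}, label="w1+w2")
    s1 = ab.prs_score(cohort, w1).scores
    s2 = ab.prs_score(cohort, w2).scores
    assert np.allclose(s1 + s2, ab.prs_score(cohort, wsum).scores)


def test_prs_reports_unresolved_weights():
    cohort = prs_cohort()
    res = ab.prs_score(cohort, ab.WeightTable({"rs1": 1.0, "rsNOPE": 2.0}, label="x"))
    assert res.unresolved == ["rsNOPE"]
    with pytest.raises(DegenerateInputError):
        ab.prs_score(cohort, ab.WeightTable({"rsNOPE": 2.0}, label="none"))


def test_prs_vs_ancestry_zero_variance_errors():
    res = ab.PRSResult("flat", ["a", "b", "c"], np.zeros(3), 1)
    with pytest.raises(DegenerateInputError, match="zero variance"):
        ab.prs_vs_ancestry(res, np.array([0.7, 0.8, 0.9]))


def test_eur_weighted_score_anticorrelates_with_african_fraction():
    # weights on EUR-enriched variants: higher AFR fraction -> lower score
    cfg = ab.SimulationConfig(n_cases=1, n_controls=1, alpha=0.8, generations=12,
                              chrom_map=[("chr1", 100_000_000, 1.0)], seed=55)
    tracts = ab.simulate_tracts(cfg, n_individuals=3000)
    variants = [make_variant(pos=1_000_000 + i * 2_000_000, rsid=f"rs{i}",
                             f_afr=0.0, f_eur=0.2) for i in range(20)]
    cohort = ab.place_alleles(tracts, variants, seed=56)
    w = ab.WeightTable({f"rs{i}": 1.0 for i in range(20)}, label="eur_private")
    scores = ab.prs_score(cohort, w)
    corr = ab.prs_vs_ancestry(scores, tracts.afr_fraction())
    row = corr[corr.stratum == "all"].iloc[0]
    assert row["r"] < 0 and row["p"] < 1e-3


def test_ancestry_neutral_weights_give_near_zero_correlation():
    cfg = ab.SimulationConfig(n_cases=1, n_controls=1, alpha=0.8, generations=12,
                              chrom_map=[("chr1", 100_000_000, 1.0)], seed=57)
    tracts = ab.simulate_tracts(cfg, n_individuals=3000)
    variants = [make_variant(pos=1_000_000 + i * 2_000_000, rsid=f"rs{i}",
                             f_afr=0.2, f_eur=0.2) for i in range(10)]
    cohort = ab.place_alleles(tracts, variants, seed=58)
    w = ab.WeightTable({f"rs{i}": 1.0 for i in range(10)}, label="neutral")
    corr = ab.prs_vs_ancestry(ab.prs_score(cohort, w), tracts.afr_fraction())
    assert abs(corr.iloc[0]["r"]) < 4 / np.sqrt(3000)


# -- site pi -----------------------------------------------------------------

@pytest.mark.parametrize("c_ref, c_alt, expected", [
    (1, 1, 1.0),
    (5, 0, 0.0),
    (3, 1, 0.5),
])
def test_site_pi_examples(c_ref, c_alt, expected):
    assert ab.site_pi(c_ref, c_alt) == expected


def test_site_pi_equals_pairwise_enumeration_up_to_n12():
    for n in range(2, 13):
        for c_alt in range(0, n + 1):
            chroms = [1] * c_alt + [0] * (n - c_alt)
            pairs = list(itertools.combinations(chroms, 2))
            brute = sum(a != b for a, b in pairs) / len(pairs)
            assert ab.site_pi(n - c_alt, c_alt) == pytest.approx(brute, rel=1e-12)


def test_site_pi_needs_two_chromosomes():
    with pytest.raises(DegenerateInputError):
        ab.site_pi(1, 0)


# -- adjusted gene pi ---------------------------------------------------------

def diversity_cohort():
    variants = [make_variant(pos=150, rsid="rs1", gene="G"),
                make_variant(pos=250, rsid="rs2", gene="G"),
                make_variant(pos=900, rsid="rsOut", gene="G")]
    gts = [[(0, 1), (0, 0), (0, 1)],
           [(1, 0), (0, 0), (0, 0)],
           [(0, 0), (0, 0), (0, 0)]]
    return make_cohort(gts, variants, ["case", "case", "control"])


def test_adjusted_pi_definition_single_site():
    # one polymorphic site with pi=0.5 in a 100 bp CDS -> 0.005
    variants = [make_variant(pos=150, rsid="rs1", gene="G")]
    cohort = make_cohort([[(0, 1)], [(0, 0)]], variants)
    cds = pd.DataFrame({"gene": ["G"], "chrom": ["chr1"], "start": [100], "end": [200]})
    res = ab.adjusted_gene_pi(cohort, cds)[0]
    assert ab.site_pi(3, 1) == 0.5
    assert res.pi_adj == pytest.approx(0.005)
    assert res.pi_per_observed_site == pytest.approx(0.5)
    assert res.n_sites_observed == 1 and res.cds_length == 100


def test_adjusted_pi_no_polymorphic_sites_is_zero():
    variants = [make_variant(pos=150, rsid="rs1", gene="G")]
    cohort = make_cohort([[(0, 0)], [(0, 0)]], variants)
    cds = pd.DataFrame({"gene": ["G"], "chrom": ["chr1"], "start": [100], "end": [200]})
    assert ab.adjusted_gene_pi(cohort, cds)[0].pi_adj == 0.0


def test_adjusted_pi_invariant_to_interval_split_and_sample_order():
    cohort = diversity_cohort()
    whole = pd.DataFrame({"gene": ["G"], "chrom": ["chr1"], "start": [100], "end": [300]})
    split = pd.DataFrame({"gene": ["G", "G"], "chrom": ["chr1", "chr1"],
                          "start": [100, 200], "end": [200, 300]})
    r1 = ab.adjusted_gene_pi(cohort, whole)[0]
    r2 = ab.adjusted_gene_pi(cohort, split)[0]
    assert r1.pi_adj == r2.pi_adj and r1.cds_length == r2.cds_length
    shuffled = cohort.subset([2, 0, 1])
    r3 = ab.adjusted_gene_pi(shuffled, whole, stratum="all")[0]
    assert r3.pi_adj == r1.pi_adj


def test_strata_from_identical_frequencies_agree(tiny_map):
    # exchangeability: random halves of one cohort give matching pi_adj on average
    cfg = ab.SimulationConfig(n_cases=1, n_controls=1, alpha=0.8,
                              chrom_map=tiny_map, seed=77)
    tracts = ab.simulate_tracts(cfg, n_individuals=400)
    variants = [make_variant(pos=500_000 + i * 10, rsid=f"rs{i}", gene="G",
                             f_afr=0.1, f_eur=0.1) for i in range(5)]
    cohort = ab.place_alleles(tracts, variants, seed=78)
    cds = pd.DataFrame({"gene": ["G"], "chrom": ["chr1"], "start": [499_000], "end": [501_000]})
    rng = np.random.default_rng(79)
    diffs = []
    for _ in range(100):
        perm = rng.permutation(cohort.n_samples)
        a = ab.adjusted_gene_pi(cohort.subset(perm[:200]), cds)[0].pi_adj
        b = ab.adjusted_gene_pi(cohort.subset(perm[200:]), cds)[0].pi_adj
        diffs.append(a - b)
    scale = ab.adjusted_gene_pi(cohort, cds)[0].pi_adj
    assert abs(np.mean(diffs)) < 0.05 * scale


def test_homozygous_ancestry_conditioning():
    from conftest import uniform_tracts

    tracts = uniform_tracts(["S0", "S1"], {"chr1": 1000}, "AFR")
    mask = ab.samples_homozygous_ancestry(tracts, "chr1", 0, 1000, "AFR")
    assert mask.tolist() == [True, True]
    assert ab.samples_homozygous_ancestry(tracts, "chr1", 0, 1000, "EUR").tolist() == [False, False]


# -- down-sampling ------------------------------------------------------------

def test_downsample_full_size_returns_input():
    cohort = diversity_cohort()
    reps = ab.downsample_strata(cohort, {"case": 2, "control": 1}, k=3, seed=1)
    for rep in reps:
        assert rep.samples == cohort.samples
        assert np.array_equal(rep.alleles, cohort.alleles)


def test_downsample_replicates_are_seed_deterministic(demo_sim):
    _, _, cohort, _ = demo_sim
    a = ab.downsample_strata(cohort, {"case": 20, "control": 50}, k=10, seed=5)
    b = ab.downsample_strata(cohort, {"case": 20, "control": 50}, k=10, seed=5)
    assert len(a) == 10
    for ra, rb in zip(a, b):
        assert ra.samples == rb.samples
    c = ab.downsample_strata(cohort, {"case": 20, "control": 50}, k=1, seed=6)
    assert c[0].samples != a[0].samples


def test_downsample_target_exceeding_stratum_errors(demo_sim):
    _, _, cohort, _ = demo_sim
    with pytest.raises(ConfigError, match="exceeds"):
        ab.downsample_strata(cohort, {"case": 10_000}, k=1, seed=0)


def test_downsampled_pi_is_unbiased_for_full_cohort(tiny_map):
    cfg = ab.SimulationConfig(n_cases=1, n_controls=1, alpha=0.8,
                              chrom_map=tiny_map, seed=88)
    tracts = ab.simulate_tracts(cfg, n_individuals=500)
    variants = [make_variant(pos=500_000 + i * 10, rsid=f"rs{i}", gene="G",
                             f_afr=0.15, f_eur=0.15) for i in range(4)]
    cohort = ab.place_alleles(tracts, variants, seed=89)
    cds = pd.DataFrame({"gene": ["G"], "chrom": ["chr1"], "start": [499_000], "end": [501_000]})
    full = ab.adjusted_gene_pi(cohort, cds)[0].pi_adj
    reps = ab.downsample_strata(cohort, {"all": 100}, k=40, seed=90)
    per_rep = [ab.adjusted_gene_pi(rep, cds) for rep in reps]
    summary = replicate_summary(per_rep)
    mean = summary.loc[0, "pi_adj_mean"]
    sd = summary.loc[0, "pi_adj_sd"]
    assert abs(mean - full) < 4 * sd / np.sqrt(len(reps))
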