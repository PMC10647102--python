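"""Burden statistics: variance explained, excess cases, association tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import admixburden as ab
from admixburden.burden import (
    OR_MIN_MAF,
    check_printed_consistency,
    round_half_away,
)
from admixburden.errors import DegenerateInputError

from conftest import make_cohort, make_variant


# -- variance explained -----------------------------------------------------

@pytest.mark.parametrize("p, orv, pct", [
    (0.045, 2.07, 4.55),   # NOD2 R702W, European side
    (0.023, 3.00, 5.42),   # NOD2 1007fs, European side
    (0.006, 2.30, 0.83),   # SDF2L1 R161H, African American side
    (0.07, 0.49, 6.63),    # IL23R R381Q, European side
])
def test_variance_explained_matches_printed_cells(p, orv, pct):
    assert round(100 * ab.variance_explained(p, orv), 2) == pct


def test_variance_explained_zero_at_or_one():
    assert ab.variance_explained(0.3, 1.0) == 0.0


@given(p=st.floats(0.001, 0.999), orv=st.floats(0.05, 20.0))
@settings(max_examples=200, derandomize=True)
def test_variance_explained_invariant_under_or_inversion(p, orv):
    assert ab.variance_explained(p, orv) == pytest.approx(
        ab.variance_explained(p, 1.0 / orv), rel=1e-9)


@given(p=st.floats(0.01, 0.49), orv=st.floats(1.1, 5.0))
@settings(max_examples=100, derandomize=True)
def test_variance_explained_maximized_at_half(p, orv):
    assert ab.variance_explained(0.5, orv) >= ab.variance_explained(p, orv)


# -- excess cases ------------------------------------------------------------

@pytest.mark.parametrize("p, orv, xs", [
    (0.045, 2.07, 77),  # NOD2 R702W EU
    (0.023, 3.00, 79),  # NOD2 1007fs EU
    (0.070, 1.17, 19),  # HGFAC R516H EU
])
def test_excess_cases_match_printed_cells(p, orv, xs):
    assert round_half_away(ab.excess_cases(p, orv)) == xs


def test_excess_cases_zero_at_or_one_exactly():
    for p in (0.001, 0.01, 0.07, 0.3):
        assert ab.excess_cases(p, 1.0) == 0.0


@given(p=st.floats(0.001, 0.3), o1=st.floats(0.2, 5.0), o2=st.floats(0.2, 5.0))
@settings(max_examples=200, derandomize=True)
def test_excess_cases_strictly_increasing_in_or(p, o1, o2):
    lo, hi = sorted((o1, o2))
    if hi - lo > 1e-9:
        assert ab.excess_cases(p, lo) < ab.excess_cases(p, hi)


@given(p=st.floats(0.001, 0.3), orv=st.floats(0.2, 5.0))
@settings(max_examples=200, derandomize=True)
def test_excess_cases_sign_matches_or(p, orv):
    xs = ab.excess_cases(p, orv)
    if abs(orv - 1.0) > 1e-9:
        assert math.copysign(1, xs) == math.copysign(1, orv - 1.0)


def test_excess_table_reproduces_input_odds_ratio():
    # rebuild the 2x2 from the solve's cells: OR must come back exactly
    p, orv, K, N = 0.03, 1.8, 0.01, 100_000
    het = 2 * p * (1 - p) * N
    e0 = het * K
    b = het - e0
    d = (1 - p) ** 2 * N - (N * K - e0)
    x1 = b * N * K / (d + b)
    x = ab.excess_cases(p, orv) + x1
    assert x * d / (b * (N * K - x)) == pytest.approx(orv, rel=1e-9)


def test_worked_example_scenario():
    # p=0.01, OR=1.3: ~25 observed vs ~20 null heterozygous cases per 100,000,
    # i.e. an excess of ~5; the integer-stepped arithmetic differs by <= 1.
    ex = ab.load_worked_example()
    xs = ab.excess_cases(ex["allele_frequency"], ex["odds_ratio"],
                         prevalence=ex["prevalence"], n=ex["population_size"])
    assert abs(xs - ex["expected_excess"]) <= 1.0


def test_pooled_carrier_excess_matches_printed_41():
    t = ab.ContingencyTable2x2(a=405, b=318, c=1744 - 405, d=1644 - 318)
    assert round(ab.odds_ratio(t), 2) == 1.26
    pooled = (405 + 318) / (1744 + 1644)
    assert round_half_away(ab.excess_cases_carrier(pooled, 1.26)) == 41


# -- odds ratio and Fisher ---------------------------------------------------

def test_odds_ratio_printed_carrier_counts():
    t = ab.ContingencyTable2x2(405, 318, 1339, 1326)
    assert round(ab.odds_ratio(t), 2) == 1.26


def test_odds_ratio_no_association_is_one():
    assert ab.odds_ratio(ab.ContingencyTable2x2(7, 7, 13, 13)) == 1.0


def test_odds_ratio_worked_example_cells():
    # corrected hom-ref control cell 97030 (printed 98030 breaks the margins)
    assert round(ab.odds_ratio(ab.ContingencyTable2x2(25, 1960, 975, 97030)), 2) == 1.27
    assert round(ab.odds_ratio(ab.ContingencyTable2x2(20, 1960, 980, 97030)), 2) == 1.01


def test_odds_ratio_zero_margin_rejected():
    with pytest.raises(DegenerateInputError):
        ab.odds_ratio(ab.ContingencyTable2x2(1, 0, 1, 1))


def test_fisher_diagonal_table():
    assert ab.fisher_test(ab.ContingencyTable2x2(5, 0, 0, 5)) == pytest.approx(2 / 252)


def test_fisher_empty_exposure_column():
    assert ab.fisher_test(ab.ContingencyTable2x2(0, 0, 3, 7)) == 1.0


@given(a=st.integers(0, 12), b=st.integers(0, 12), c=st.integers(0, 12), d=st.integers(0, 12))
@settings(max_examples=300, derandomize=True)
def test_fisher_matches_scipy(a, b, c, d):
    t = ab.ContingencyTable2x2(a, b, c, d)
    _, p_ref = sps.fisher_exact([[a, b], [c, d]])
    assert ab.fisher_test(t) == pytest.approx(min(p_ref, 1.0), rel=1e-9, abs=1e-12)


# -- rarity, carriers, frequencies -------------------------------------------

@pytest.mark.parametrize("af, cls", [
    (0.0005, "ultra_rare"), (0.001, "ultra_rare"),
    (0.0011, "very_rare"), (0.01, "very_rare"),
    (0.011, "rare"), (0.023, "rare"), (0.049, "rare"),
    (0.05, "common"), (0.07, "common"),
])
def test_classify_rarity_boundaries(af, cls):
    assert ab.classify_rarity(af) == cls


def test_carrier_status_counts_distinct_variants():
    variants = [make_variant(pos=10 + i, rsid=f"rs{i}") for i in range(4)]
    gts = [
        [(0, 0), (0, 0), (0, 0), (0, 0)],  # non-carrier
        [(1, 1), (0, 0), (0, 0), (0, 0)],  # hom alt at one variant: count 1
        [(0, 1), (1, 0), (0, 1), (1, 1)],  # four distinct variants
    ]
    cohort = make_cohort(gts, variants)
    carrier, counts = ab.carrier_status(cohort)
    assert carrier.tolist() == [False, True, True]
    assert counts.tolist() == [0, 1, 4]


def test_allele_frequency_direct_count():
    cohort = make_cohort([[(0, 1)], [(1, 1)]], [make_variant()])
    assert ab.allele_frequency(cohort, 0) == 0.75


def test_allele_frequency_zero_and_missing_handling():
    cohort = make_cohort([[(0, 0)], [(-1, -1)], [(0, 1)]], [make_variant()])
    # 1 alt over 4 observed calls (missing sample excluded from denominator)
    assert ab.allele_frequency(cohort, 0) == 0.25
    none = make_cohort([[(0, 0)], [(0, 0)]], [make_variant()])
    assert ab.allele_frequency(none, 0) == 0.0


# -- table paths and aggregation ---------------------------------------------

def test_burden_rows_from_printed_table_aggregate(cd_table):
    rows = ab.burden_rows_from_table(cd_table, "eu_maf", "eu_or")
    by_rsid = {r.rsid: r for r in rows}
    assert by_rsid["rs2066844"].xs_rounded == 77
    assert by_rsid["rs2066847"].xs_rounded == 79
    assert by_rsid["rs16844401"].xs_rounded == 19
    # ultra-rare row: statistics computed but flagged as unreliable-OR regime
    assert by_rsid["rs104895438"].or_flag == "maf_below_0.001"
    risk8 = {r.rsid for r in rows if r.direction == "risk" and r.af_eur > 0.01}
    xs, ve = ab.aggregate_burden(rows, subset=risk8)
    # printed per-variant cells sum to 271; recomputation from the printed
    # 2-d.p. MAF/OR gives 265.4 (the difference sits in the flagged cells)
    assert xs == pytest.approx(265.39, abs=0.05)
    printed = cd_table.df.set_index("rsid").loc[sorted(risk8), "eu_xs"].astype(int).sum()
    assert printed == 271


def test_aggregate_empty_subset_is_zero(cd_table):
    rows = ab.burden_rows_from_table(cd_table, "eu_maf", "eu_or")
    assert ab.aggregate_burden(rows, subset=set()) == (0.0, 0.0)


def test_build_burden_table_cohort_path():
    variants = [make_variant(pos=10, rsid="rs1", f_eur=0.02),
                make_variant(pos=20, rsid="rs2", f_eur=0.2)]
    gts = [[(0, 1), (1, 1)], [(0, 0), (0, 1)], [(0, 0), (0, 0)], [(1, 0), (0, 0)]]
    phen = ["case", "case", "control", "control"]
    cohort = make_cohort(gts, variants, phen)
    rows = ab.build_burden_table(cohort)
    r1 = rows[0]
    assert r1.af_case == 0.25 and r1.af_control == 0.25
    assert r1.n_carriers_case == 1 and r1.n_carriers_control == 1
    assert r1.rarity == "rare"
    assert 0 <= r1.fisher_p <= 1
    # allele-level 2x2 check against a direct Fisher computation
    t = ab.ContingencyTable2x2(1, 1, 3, 3)
    assert r1.fisher_p == ab.fisher_test(t)


def test_build_burden_table_flags_sub_threshold_maf():
    variants = [make_variant(pos=10, rsid="rs1")]
    gts = [[(0, 0)]] * 600 + [[(0, 1)]]
    phen = ["case"] * 300 + ["control"] * 301
    cohort = make_cohort(gts, variants, phen)
    rows = ab.build_burden_table(cohort)
    assert ab.allele_frequency(cohort, 0) < OR_MIN_MAF
    assert rows[0].or_flag == "maf_below_0.001"
    assert np.isnan(rows[0].or_hat)


# -- EP filter ---------------------------------------------------------------

def test_ep_filter_pathogenic_range(ep_table):
    kept = ab.ep_filter(ep_table, threshold=0.0022)
    assert sorted(kept.df["ep_score"]) == [0.0008, 0.001, 0.002, 0.002]
    assert set(kept.df["rsid"]) == {"rs61739341", "rs140866472", "rs138674524", "rs112519623"}


def test_ep_filter_degenerate_thresholds(ep_table):
    assert len(ab.ep_filter(ep_table, threshold=0.0)) == 0
    assert len(ab.ep_filter(ep_table, threshold=1.0)) == len(ep_table)


# -- printed-cell consistency audit -------------------------------------------

def test_printed_cell_consistency_flags():
    df = check_printed_consistency().set_index(["rsid", "side"])
    # every printed variance-explained cell reproduces from printed MAF/OR
    assert df["ve_consistent"].all()
    # excess-case cells that reproduce from printed inputs
    for rsid in ("rs2066844", "rs2066847", "rs16844401", "rs2228015", "rs34215892"):
        assert df.loc[(rsid, "eu"), "xs_consistent"]
    # cells computed from unrounded cohort frequencies: flagged, not matched
    for rsid, computed in [("rs13107325", 23), ("rs73166641", 6), ("rs2066845", 37)]:
        assert not df.loc[(rsid, "eu"), "xs_consistent"]
        assert df.loc[(rsid, "eu"), "computed_xs"] == computed
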