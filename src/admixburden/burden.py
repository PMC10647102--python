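"""Per-variant rare-variant burden statistics.

The statistics here quantify how much disease burden a set of rare coding
variants carries in a population:

* **Variance explained** — the liability-scale contribution of a biallelic
  variant, ``2 p (1-p) (ln OR)^2`` with ``p`` the ascertained-allele
  frequency and ``OR`` the per-allele odds ratio (reported x100 as percent).
* **Excess cases per 100,000** — fix the population at N = 100,000 with
  disease prevalence K, put the expected heterozygote carriers in a 2x2
  carrier-by-status table with carrier controls and the homozygous-reference
  pool held at their null expectations, and solve for the carrier-case count
  ``x(OR)`` that produces the observed odds ratio. The excess is
  ``x(OR) - x(1)``: observed minus the count that makes the same table
  multiplicative-null. It is zero exactly at OR = 1, strictly increasing in
  OR, and negative for protective variants. Alternate-allele homozygotes are
  disregarded (negligible for rare alleles); a carrier-frequency variant of
  the procedure pools all carriers instead of heterozygotes.
* **Association** — Fisher's exact test on allele-level 2x2 tables, without
  covariate adjustment; carrier status defined as >= 1 alternate copy.

Rarity classes follow the EU-frequency conventions: ultra-rare
(MAF <= 0.001), very rare (0.001 < MAF <= 0.01), rare (0.01 < MAF < 0.05),
common (MAF >= 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PhasedCohort
from .errors import ConfigError, DegenerateInputError
from .variants import VariantTable

ULTRA_RARE = "ultra_rare"
VERY_RARE = "very_rare"
RARE = "rare"
COMMON = "common"

#: below this cohort MAF an odds-ratio estimate is considered unreliable
OR_MIN_MAF = 0.001


def round_half_away(x):
    """Round to nearest integer, halves away from zero (reporting layer only)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure-by-status counts: a/b exposed cases/controls, c/d unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigError("contingency counts must be non-negative")

    @classmethod
    def from_carriers(cls, carrier, case_mask):
        carrier = np.asarray(carrier, dtype=bool)
        case_mask = np.asarray(case_mask, dtype=bool)
        return cls(
            a=int((carrier & case_mask).sum()),
            b=int((carrier & ~case_mask).sum()),
            c=int((~carrier & case_mask).sum()),
            d=int((~carrier & ~case_mask).sum()),
        )

    @classmethod
    def from_allele_counts(cls, alt_case, n_case_alleles, alt_control, n_control_alleles):
        return cls(
            a=int(alt_case), b=int(alt_control),
            c=int(n_case_alleles - alt_case), d=int(n_control_alleles - alt_control),
        )


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Cross-product odds ratio (a*d)/(b*c); requires b, c > 0."""
    if table.b == 0 or table.c == 0:
        raise DegenerateInputError("odds ratio undefined: zero margin (b or c is 0)")
    return (table.a * table.d) / (table.b * table.c)


def fisher_test(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities <= observed.

    Computed with exact integer numerators over the common denominator
    C(n, a+c), so probability ties are resolved exactly rather than through a
    floating-point epsilon; agrees with ``scipy.stats.fisher_exact``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = nums[a - lo]
    return sum(x for x in nums if x <= observed) / math.comb(n, c1)


def variance_explained(p: float, odds_ratio: float) -> float:
    """Liability-scale variance fraction 2p(1-p)(ln OR)^2 (multiply by 100 for %)."""
    if not 0.0 < p < 1.0:
        raise ConfigError(f"allele frequency must be in (0, 1), got {p}")
    if not odds_ratio > 0:
        raise ConfigError(f"odds ratio must be > 0, got {odds_ratio}")
    return 2.0 * p * (1.0 - p) * math.log(odds_ratio) ** 2


def _excess_from_exposure(exposed_freq, unexposed_freq, or_, prevalence, n):
    """Excess exposed cases: table solve x(OR) minus the null solve x(1).

    Exposed controls ``B`` and the unexposed-control pool ``D`` are held at
    their null expectations; the case column is rebalanced to produce the
    target odds ratio.
    """
    nk = n * prevalence
    e0 = exposed_freq * n * prevalence
    b = exposed_freq * n - e0
    d = unexposed_freq * n - (nk - e0)
    if d <= 0 or or_ * b + d == 0:
        raise DegenerateInputError("degenerate excess-case table (no unexposed controls)")

    def solve(r):
        return r * b * nk / (d + r * b)

    return solve(or_) - solve(1.0)


def excess_cases(p: float, odds_ratio: float, prevalence: float = 0.01, n: int = 100_000) -> float:
    """Excess heterozygote cases per ``n`` people (negative for OR < 1).

    ``p`` is the allele frequency; heterozygote frequency is ``2p(1-p)`` and
    alternate homozygotes are disregarded. Continuous value — round at the
    reporting layer only.
    """
    if not 0.0 < p < 1.0:
        raise ConfigError(f"allele frequency must be in (0, 1), got {p}")
    if not odds_ratio > 0:
        raise ConfigError(f"odds ratio must be > 0, got {odds_ratio}")
    het = 2.0 * p * (1.0 - p)
    hom_ref = (1.0 - p) ** 2
    return _excess_from_exposure(het, hom_ref, odds_ratio, prevalence, n)


def excess_cases_carrier(carrier_freq: float, odds_ratio: float,
                         prevalence: float = 0.01, n: int = 100_000) -> float:
    """Excess carrier cases per ``n`` people, with pooled carrier frequency."""
    if not 0.0 < carrier_freq < 1.0:
        raise ConfigError(f"carrier frequency must be in (0, 1), got {carrier_freq}")
    if not odds_ratio > 0:
        raise ConfigError(f"odds ratio must be > 0, got {odds_ratio}")
    return _excess_from_exposure(carrier_freq, 1.0 - carrier_freq, odds_ratio, prevalence, n)


def classify_rarity(af_eur: float) -> str:
    """Rarity class from the European-cohort frequency of the ascertained allele."""
    if not 0.0 <= af_eur <= 1.0:
        raise ConfigError(f"allele frequency must be in [0, 1], got {af_eur}")
    if af_eur <= 0.001:
        return ULTRA_RARE
    if af_eur <= 0.01:
        return VERY_RARE
    if af_eur < 0.05:
        return RARE
    return COMMON


def allele_frequency(cohort: PhasedCohort, variant, stratum="all") -> float:
    """Alternate-allele frequency in a stratum; missing calls excluded."""
    j = variant if isinstance(variant, (int, np.integer)) else cohort.variant_index(variant)
    mask = cohort.stratum_mask(stratum)
    if not mask.any():
        raise DegenerateInputError("allele frequency over an empty stratum")
    calls = cohort.alleles[mask, j, :]
    observed = calls >= 0
    denom = int(observed.sum())
    if denom == 0:
        raise DegenerateInputError("all genotypes missing in stratum")
    return float(calls[observed].sum() / denom)


def carrier_status(cohort: PhasedCohort, variant_set=None):
    """Carrier flag (>= 1 alt copy at any set variant) and per-individual variant count.

    The count is the number of distinct set variants at which the individual
    carries at least one alternate copy.
    """
    if variant_set is None:
        vidx = np.arange(cohort.n_variants)
    else:
        vidx = np.array([v if isinstance(v, (int, np.integer)) else cohort.variant_index(v)
                         for v in variant_set])
    counts_per_variant = (cohort.alleles[:, vidx, :] == 1).any(axis=2)
    counts = counts_per_variant.sum(axis=1).astype(int)
    return counts > 0, counts


@dataclass
class BurdenRow:
    """Derived statistics for one variant."""

    variant: str
    gene: str = ""
    rsid: str = ""
    af_afr: float = float("nan")
    af_eur: float = float("nan")
    af_case: float = float("nan")
    af_control: float = float("nan")
    ratio: float = float("nan")
    or_hat: float = float("nan")
    or_flag: str = ""
    ve_pct: float = float("nan")
    xs: float = float("nan")
    xs_rounded: object = None
    rarity: str = ""
    fisher_p: float = float("nan")
    n_carriers_case: object = None
    n_carriers_control: object = None
    direction: str = ""

    def to_dict(self):
        return dict(self.__dict__)


def burden_rows_from_table(table: VariantTable, maf_col: str, or_col: str,
                           prevalence: float = 0.01, n: int = 100_000) -> list:
    """Burden rows from a frequency-only annotation table (summary-AF path).

    Uses the printed/summary allele frequency ``maf_col`` and odds ratio
    ``or_col``; rows with a missing OR, or with MAF outside (0, 1), get no
    VE/excess and carry a flag. Rows with MAF < 0.001 keep their statistics
    but are flagged as unreliable-OR territory.
    """
    rows = []
    df = table.df
    for _, r in df.iterrows():
        p = pd.to_numeric(pd.Series([r.get(maf_col)]), errors="coerce").iloc[0]
        orv = pd.to_numeric(pd.Series([r.get(or_col)]), errors="coerce").iloc[0]
        row = BurdenRow(
            variant=str(r.get("rsid", r.get("variant", ""))),
            gene=str(r.get("gene", "")),
            rsid=str(r.get("rsid", "")),
            af_afr=float(r["aa_maf"]) if "aa_maf" in df.columns else float("nan"),
            af_eur=float(r["eu_maf"]) if "eu_maf" in df.columns else float("nan"),
            direction=str(r.get("direction", "")),
        )
        if np.isfinite(row.af_afr) and np.isfinite(row.af_eur) and row.af_eur > 0:
            row.ratio = row.af_afr / row.af_eur
        if "eu_maf" in df.columns and np.isfinite(row.af_eur):
            row.rarity = classify_rarity(row.af_eur)
        if not np.isfinite(orv):
            row.or_flag = "no_or"
        elif not (0.0 < p < 1.0):
            row.or_flag = "maf_degenerate"
        else:
            row.or_hat = float(orv)
            row.ve_pct = 100.0 * variance_explained(float(p), float(orv))
            row.xs = excess_cases(float(p), float(orv), prevalence=prevalence, n=n)
            row.xs_rounded = round_half_away(row.xs)
            if p < OR_MIN_MAF:
                row.or_flag = "maf_below_0.001"
        rows.append(row)
    return rows


def build_burden_table(cohort: PhasedCohort, variant_table: VariantTable | None = None,
                       prevalence: float = 0.01, n: int = 100_000,
                       carrier_level: bool = False) -> list:
    """Burden rows from genotypes and phenotypes (cohort path).

    Per variant: case/control allele frequencies, a Fisher exact test on the
    allele-level 2x2 table (or carrier-level when ``carrier_level``), the
    cross-product odds ratio (omitted and flagged when the cohort MAF is
    below 0.001), variance explained and excess cases computed at the
    control-cohort allele frequency, and carrier counts per stratum.
    """
    case = cohort.case_mask()
    n_case, n_control = int(case.sum()), int((~case).sum())
    if n_case == 0 or n_control == 0:
        raise DegenerateInputError("burden table needs both cases and controls")
    rows = []
    for j, v in enumerate(cohort.variants):
        af_case = allele_frequency(cohort, j, "case")
        af_control = allele_frequency(cohort, j, "control")
        af_all = allele_frequency(cohort, j, "all")
        carrier, _ = carrier_status(cohort, [j])
        if carrier_level:
            t = ContingencyTable2x2.from_carriers(carrier, case)
        else:
            calls = cohort.alleles[:, j, :]
            obs_case = int((calls[case] >= 0).sum())
            obs_control = int((calls[~case] >= 0).sum())
            t = ContingencyTable2x2.from_allele_counts(
                int((calls[case] == 1).sum()), obs_case,
                int((calls[~case] == 1).sum()), obs_control)
        row = BurdenRow(
            variant=v.key, gene=v.gene, rsid=v.rsid,
            af_afr=v.f_afr, af_eur=v.f_eur,
            af_case=af_case, af_control=af_control,
            rarity=classify_rarity(v.f_eur),
            fisher_p=fisher_test(t),
            n_carriers_case=int((carrier & case).sum()),
            n_carriers_control=int((carrier & ~case).sum()),
            direction=v.direction,
        )
        if v.f_eur > 0:
            row.ratio = v.f_afr / v.f_eur
        if af_all < OR_MIN_MAF:
            row.or_flag = "maf_below_0.001"
        elif t.b == 0 or t.c == 0:
            row.or_flag = "zero_margin"
        else:
            row.or_hat = odds_ratio(t)
            if 0.0 < af_control < 1.0 and row.or_hat > 0:
                row.ve_pct = 100.0 * variance_explained(af_control, row.or_hat)
                row.xs = excess_cases(af_control, row.or_hat, prevalence=prevalence, n=n)
                row.xs_rounded = round_half_away(row.xs)
        rows.append(row)
    return rows


def aggregate_burden(rows, subset=None):
    """Summed excess cases and summed %VE over a named subset of rows.

    ``subset`` is a container of variant identifiers (key or rsid); ``None``
    aggregates every row with a finite statistic. Risk variants contribute
    positive excess, protective variants negative.
    """
    total_xs = 0.0
    total_ve = 0.0
    for row in rows:
        if subset is not None and row.variant not in subset and row.rsid not in subset:
            continue
        if np.isfinite(row.xs):
            total_xs += row.xs
        if np.isfinite(row.ve_pct):
            total_ve += row.ve_pct
    return total_xs, total_ve


def ep_filter(table: VariantTable, threshold: float = 0.0022) -> VariantTable:
    """Retain rows whose evolutionary-probability score is below ``threshold``.

    EP scores below ~0.0022 are strongly enriched for known pathogenic
    mutations; this reproduces that pathogenic-range filter.
    """
    if "ep_score" not in table.df.columns:
        raise ConfigError("variant table has no 'ep_score' column")
    kept = table.df[pd.to_numeric(table.df["ep_score"]) < threshold]
    return VariantTable(kept.reset_index(drop=True))


def check_printed_consistency(table: VariantTable | None = None,
                              prevalence: float = 0.01, n: int = 100_000) -> pd.DataFrame:
    """Recompute the %VE and excess-case cells of the packaged summary table.

    For each variant and cohort side (African American ``aa``, European
    ``eu``) with a printed odds ratio, recompute variance explained (2 d.p.)
    and excess cases (rounded) from the printed MAF/OR, and flag cells that do
    not match the printed value — those cells were evidently derived from
    unrounded cohort frequencies and are reported, not replicated. Excess
    magnitudes are compared (the table prints protective burden unsigned).
    """
    from .variants import load_cd_variant_table

    if table is None:
        table = load_cd_variant_table()
    recs = []
    for _, r in table.df.iterrows():
        for side in ("aa", "eu"):
            p = pd.to_numeric(pd.Series([r[f"{side}_maf"]]), errors="coerce").iloc[0]
            orv = pd.to_numeric(pd.Series([r[f"{side}_or"]]), errors="coerce").iloc[0]
            printed_ve = pd.to_numeric(pd.Series([r[f"{side}_ve_pct"]]), errors="coerce").iloc[0]
            printed_xs = pd.to_numeric(pd.Series([r[f"{side}_xs"]]), errors="coerce").iloc[0]
            if not (np.isfinite(orv) and 0.0 < p < 1.0):
                continue
            ve = 100.0 * variance_explained(p, orv)
            xs = excess_cases(p, orv, prevalence=prevalence, n=n)
            xs_r = round_half_away(xs)
            recs.append({
                "rsid": r["rsid"], "gene": r["gene"], "side": side,
                "maf": p, "odds_ratio": orv,
                "printed_ve_pct": printed_ve, "computed_ve_pct": round(ve, 4),
                # a printed 2-d.p. cell is consistent iff the unrounded
                # recomputation sits within half an ulp of it
                "ve_consistent": bool(np.isfinite(printed_ve) and abs(ve - printed_ve) <= 0.005 + 1e-9),
                "printed_xs": printed_xs, "computed_xs": xs_r,
                "xs_consistent": bool(np.isfinite(printed_xs) and abs(xs_r) == int(printed_xs)),
            })
    return pd.DataFrame(recs)
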