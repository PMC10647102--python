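"""Haplotype-level ancestry attribution of alternate-allele copies.

Each alternate allele copy in a phased, locally-ancestry-painted cohort lies
on exactly one tract, so it can be attributed to an African or European
haplotype background. Summed per variant (and per disease group) this gives
the African/European split of the observed rare-allele burden; summed per
individual it relates global ancestry fraction to the number of risk
variants carried. Copy counts are conserved exactly: n_afr + n_eur equals
the cohort's total alternate-copy count for the variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AFR, EUR, PhasedCohort, TractSet
from .errors import CoverageError, DegenerateInputError


@dataclass
class AttributionRow:
    """African/European copy counts for one variant."""

    variant: str
    rsid: str = ""
    gene: str = ""
    n_afr: int = 0
    n_eur: int = 0
    group: str = ""

    @property
    def n_total(self):
        return self.n_afr + self.n_eur

    @property
    def prop_afr(self):
        """African share of observed copies; None (written NA) when no copies."""
        if self.n_total == 0:
            return None
        return self.n_afr / self.n_total

    def to_dict(self):
        return {
            "variant": self.variant, "rsid": self.rsid, "gene": self.gene,
            "n_afr": self.n_afr, "n_eur": self.n_eur, "n_total": self.n_total,
            "prop_afr": float("nan") if self.prop_afr is None else self.prop_afr,
            "group": self.group,
        }


@dataclass
class AncestrySummary:
    """Per-sample global ancestry fractions and target-variant counts."""

    samples: list
    afr_fraction: np.ndarray
    n_set_variants: np.ndarray
    scope: str = "all"

    @property
    def eur_fraction(self):
        return 1.0 - self.afr_fraction

    def to_dataframe(self):
        return pd.DataFrame({
            "sample_id": self.samples,
            "afr_fraction": self.afr_fraction,
            "eur_fraction": self.eur_fraction,
            "n_set_variants": self.n_set_variants,
        })


def attribute_copies(cohort: PhasedCohort, tracts: TractSet, variants=None) -> list:
    """Attribute every alternate-allele copy to its local-ancestry background.

    Returns one :class:`AttributionRow` per variant. Raises
    :class:`CoverageError` naming sample, haplotype and variant if a copy's
    position is not covered by a tract.
    """
    if variants is None:
        variants = cohort.variants
    rows = []
    for v in variants:
        j = cohort.variant_index(v.key)
        try:
            codes = tracts.ancestry_at(v.chrom, v.pos)
        except CoverageError as exc:
            carriers = np.argwhere(cohort.alleles[:, j, :] == 1)
            who = f"sample {cohort.samples[carriers[0][0]]} haplotype {carriers[0][1]}" if len(carriers) else "no carrier"
            raise CoverageError(f"variant {v.rsid} ({who}): {exc}") from exc
        alt = cohort.alleles[:, j, :] == 1
        rows.append(AttributionRow(
            variant=v.key, rsid=v.rsid, gene=v.gene,
            n_afr=int((alt & (codes == AFR)).sum()),
            n_eur=int((alt & (codes == EUR)).sum()),
        ))
    return rows


def global_fractions(tracts: TractSet, cohort: PhasedCohort = None,
                     variant_set=None, chroms=None) -> AncestrySummary:
    """Tract-length-weighted ancestry fraction per sample, with variant counts.

    ``chroms`` restricts the scope to a chromosome subset (e.g. only the
    chromosomes that were locally painted). When a cohort is given,
    ``n_set_variants`` counts the target variants each individual carries.
    """
    afr = tracts.afr_fraction(chroms=chroms)
    if cohort is not None:
        from .burden import carrier_status

        _, counts = carrier_status(cohort, variant_set)
    else:
        counts = np.zeros(tracts.n_samples, dtype=int)
    scope = "all" if chroms is None else ",".join(chroms)
    return AncestrySummary(list(tracts.samples), afr, counts, scope=scope)


def ancestry_vs_count(summary: AncestrySummary, phenotypes=None) -> dict:
    """OLS slope and Pearson correlation of European fraction on variant count.

    Returns ``{'all': result, 'case': result, 'control': result}`` (strata
    only when phenotypes are given); each result has slope, intercept, r,
    p-value (two-sided, t distribution) and n.
    """
    def fit(eur, counts):
        if len(eur) < 3:
            raise DegenerateInputError("need >= 3 samples for regression")
        if np.ptp(counts) == 0 or np.ptp(eur) == 0:
            raise DegenerateInputError("zero variance on one axis (counts or ancestry fraction)")
        ls = stats.linregress(counts, eur)
        return {
            "slope": float(ls.slope), "intercept": float(ls.intercept),
            "r": float(ls.rvalue), "p": float(ls.pvalue), "n": int(len(eur)),
        }

    eur = summary.eur_fraction
    counts = np.asarray(summary.n_set_variants, dtype=float)
    out = {"all": fit(eur, counts)}
    if phenotypes is not None:
        phen = np.asarray(phenotypes, dtype=object)
        for stratum in ("case", "control"):
            mask = phen == stratum
            if mask.sum() >= 3:
                out[stratum] = fit(eur[mask], counts[mask])
    return out


def group_attribution(rows, group_map: dict) -> pd.DataFrame:
    """Pool attribution counts by disease group.

    ``group_map`` maps a variant identifier (key or rsid) to one or more
    group labels; a variant mapped to several groups contributes its copies
    to each. Groups with no observed copies get NA proportion and a flag.
    """
    pooled = {}
    for row in rows:
        groups = group_map.get(row.variant, group_map.get(row.rsid, []))
        if isinstance(groups, str):
            groups = [groups]
        for g in groups:
            n_afr, n_eur = pooled.get(g, (0, 0))
            pooled[g] = (n_afr + row.n_afr, n_eur + row.n_eur)
    all_groups = set()
    for gs in group_map.values():
        all_groups.update([gs] if isinstance(gs, str) else gs)
    recs = []
    for g in sorted(all_groups):
        n_afr, n_eur = pooled.get(g, (0, 0))
        total = n_afr + n_eur
        recs.append({
            "group": g, "n_afr": n_afr, "n_eur": n_eur, "n_total": total,
            "prop_afr": (n_afr / total) if total else float("nan"),
            "empty": total == 0,
        })
    return pd.DataFrame(recs)
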