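"""Model/Results facade over the analysis pipeline.

`AdmixtureBurdenModel` bundles a phased case/control cohort, its local
ancestry tracts and a variant annotation set; ``fit()`` runs the per-variant
burden statistics, haplotype-level ancestry attribution, the ancestry-vs-
variant-count regression and (optionally) PRS-vs-ancestry correlations, and
returns an `AdmixtureBurdenResults` carrying the tables with a ``summary()``
report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .attribution import ancestry_vs_count, attribute_copies, global_fractions
from .burden import aggregate_burden, build_burden_table
from .cohort import PhasedCohort, TractSet
from .prs import prs_score, prs_vs_ancestry


class AdmixtureBurdenModel:
    """Admixture-aware rare-variant burden analysis of one cohort.

    Parameters
    ----------
    cohort
        Phased genotypes with case/control phenotypes.
    tracts
        Local-ancestry tracts covering every variant position.
    prs_weights
        Optional list of :class:`~admixburden.variants.WeightTable` (e.g.
        European-derived and African-derived weight sets).
    prevalence
        Assumed disease prevalence for the excess-case computation.
    ancestry_chroms
        Optional chromosome subset for the global-ancestry scope.
    """

    def __init__(self, cohort: PhasedCohort, tracts: TractSet, prs_weights=None,
                 prevalence: float = 0.01, ancestry_chroms=None):
        self.cohort = cohort
        self.tracts = tracts
        self.prs_weights = list(prs_weights) if prs_weights else []
        self.prevalence = prevalence
        self.ancestry_chroms = ancestry_chroms

    @classmethod
    def from_files(cls, vcf, tracts_bed, phenotypes_tsv, weights=None, **kwargs):
        """Build the model from pipeline files on disk."""
        from . import io as io_formats

        cohort = io_formats.read_phased_vcf(vcf)
        cohort = io_formats.attach_phenotypes(cohort, phenotypes_tsv)
        tracts = io_formats.read_tracts(tracts_bed)
        wtables = [io_formats.read_weights(w) for w in (weights or [])]
        return cls(cohort, tracts, prs_weights=wtables, **kwargs)

    def fit(self) -> "AdmixtureBurdenResults":
        burden_rows = build_burden_table(self.cohort, prevalence=self.prevalence)
        attribution_rows = attribute_copies(self.cohort, self.tracts)
        summary = global_fractions(self.tracts, cohort=self.cohort,
                                   chroms=self.ancestry_chroms)
        regression = ancestry_vs_count(summary, phenotypes=self.cohort.phenotypes)
        prs_tables = []
        if self.prs_weights:
            scores = [prs_score(self.cohort, w) for w in self.prs_weights]
            prs_tables = prs_vs_ancestry(scores, summary.afr_fraction,
                                         phenotypes=self.cohort.phenotypes)
        return AdmixtureBurdenResults(self, burden_rows, attribution_rows,
                                      summary, regression, prs_tables)


class AdmixtureBurdenResults:
    """Fitted tables and diagnostics; see :meth:`summary`."""

    def __init__(self, model, burden_rows, attribution_rows, ancestry, regression, prs):
        self.model = model
        self.burden_rows = burden_rows
        self.attribution_rows = attribution_rows
        self.ancestry = ancestry
        self.regression = regression
        self.prs = prs

    @property
    def burden(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.burden_rows])

    @property
    def attribution(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.attribution_rows])

    def aggregate(self, subset=None):
        """(summed excess cases per 100,000, summed %VE) over a variant subset."""
        return aggregate_burden(self.burden_rows, subset=subset)

    def summary(self) -> str:
        case = self.model.cohort.case_mask()
        xs, ve = self.aggregate()
        att = self.attribution
        total = att["n_total"].sum()
        prop_afr = att["n_afr"].sum() / total if total else float("nan")
        reg = self.regression["all"]
        lines = [
            "Admixture-aware rare-variant burden analysis",
            "=" * 52,
            f"samples: {self.model.cohort.n_samples} "
            f"({int(case.sum())} cases / {int((~case).sum())} controls); "
            f"variants: {self.model.cohort.n_variants}",
            f"prevalence assumed: {self.model.prevalence:g}",
            "",
            f"summed excess cases per 100,000: {xs:+.1f}",
            f"summed variance explained: {ve:.2f}%",
            f"alt-allele copies on African haplotypes: "
            f"{att['n_afr'].sum()}/{total} ({100 * prop_afr:.1f}%)" if total else
            "alt-allele copies observed: 0",
            f"mean African ancestry fraction: {self.ancestry.afr_fraction.mean():.3f}",
            f"EUR-fraction ~ variant-count slope: {reg['slope']:+.4g} "
            f"(r={reg['r']:+.3f}, p={reg['p']:.3g}, n={reg['n']})",
        ]
        if len(self.prs):
            lines.append("")
            lines.append("PRS vs African ancestry fraction (Pearson r):")
            for _, row in self.prs.iterrows():
                lines.append(f"  {row['weight_set']} [{row['stratum']}]: "
                             f"r={row['r']:+.3f} (p={row['p']:.3g}, n={row['n']})")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<AdmixtureBurdenResults: {self.model.cohort.n_samples} samples, "
                f"{self.model.cohort.n_variants} variants>")
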