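"""Polygenic risk scores under ancestry-specific weight sets.

A PRS is the weighted sum of alternate-allele counts over the weight table's
variants. Because effect weights are estimated in a discovery cohort of a
particular ancestry, scores computed in an admixed cohort correlate with
each individual's ancestry fraction whenever the weighted variants differ in
frequency between ancestral backgrounds — the portability effect this module
quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PhasedCohort
from .errors import DegenerateInputError
from .variants import WeightTable


@dataclass
class PRSResult:
    """Per-sample scores for one weight set, plus resolution diagnostics."""

    label: str
    samples: list
    scores: np.ndarray
    n_resolved: int
    unresolved: list = field(default_factory=list)

    def to_dataframe(self):
        return pd.DataFrame({"sample_id": self.samples, "score": self.scores})


def prs_score(cohort: PhasedCohort, weights: WeightTable) -> PRSResult:
    """Score = sum over resolvable weight variants of weight x allele count.

    Weight keys are resolved against variant keys first, then rsIDs;
    unresolvable weights are reported, not silently dropped into the sum.
    """
    by_key = {v.key: j for j, v in enumerate(cohort.variants)}
    by_rsid = {v.rsid: j for j, v in enumerate(cohort.variants)}
    counts = cohort.alt_counts()
    w = np.zeros(cohort.n_variants)
    unresolved = []
    n_resolved = 0
    for key, weight in weights.items():
        j = by_key.get(key, by_rsid.get(key))
        if j is None:
            unresolved.append(key)
        else:
            w[j] += weight
            n_resolved += 1
    if n_resolved == 0:
        raise DegenerateInputError(
            f"no weight in set {weights.label!r} resolves against the cohort's variants")
    return PRSResult(weights.label, list(cohort.samples), counts @ w, n_resolved, unresolved)


def prs_vs_ancestry(results, afr_fraction, phenotypes=None) -> pd.DataFrame:
    """Pearson correlation of each weight set's score with African fraction.

    ``results`` is a PRSResult or list of them. Returns one row per weight
    set and stratum ('all' plus case/control when phenotypes are given) with
    r, the two-sided p-value and n.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    afr = np.asarray(afr_fraction, dtype=float)
    recs = []
    for res in results:
        strata = {"all": np.ones(len(afr), dtype=bool)}
        if phenotypes is not None:
            phen = np.asarray(phenotypes, dtype=object)
            strata["case"] = phen == "case"
            strata["control"] = phen == "control"
        for name, mask in strata.items():
            if mask.sum() < 3:
                continue
            s = res.scores[mask]
            a = afr[mask]
            if np.ptp(s) == 0 or np.ptp(a) == 0:
                raise DegenerateInputError(
                    f"zero variance in {name} stratum for weight set {res.label!r}")
            r, p = stats.pearsonr(a, s)
            recs.append({"weight_set": res.label, "stratum": name,
                         "r": float(r), "p": float(p), "n": int(mask.sum())})
    return pd.DataFrame(recs)
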