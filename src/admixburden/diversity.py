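"""Coding-region nucleotide diversity with cohort matching.

Per-site nucleotide diversity for a biallelic site observed on ``n``
chromosomes with ``c_ref``/``c_alt`` allele counts is the fraction of
unordered chromosome pairs that differ, ``2 c_ref c_alt / (n (n-1))``.

The gene-level statistic divides the sum of per-site diversity over the
polymorphic sites inside a gene's CDS by the total CDS length (unobserved
positions contribute zero). Because cohorts sequenced or filtered
differently present different numbers of CDS sites, the number of observed
sites is carried along and an explicitly labelled coverage-adjusted column
(``pi_sum / n_sites_observed``) is reported beside the per-CDS-base value —
both are reported, neither silently substituted.

Cohort matching utilities: restrict a stratum to individuals homozygous for
one ancestry across a gene's CDS span, and down-sample a larger cohort to a
target size over seeded replicates so diversity comparisons are not driven
by sample-size ascertainment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ANCESTRY_CODES, PhasedCohort, TractSet
from .errors import ConfigError, DegenerateInputError


def site_pi(c_ref: int, c_alt: int) -> float:
    """Pairwise-difference fraction at one site over all chromosome pairs."""
    n = c_ref + c_alt
    if n < 2:
        raise DegenerateInputError("site diversity needs >= 2 chromosomes")
    return 2.0 * c_ref * c_alt / (n * (n - 1))


@dataclass
class DiversityResult:
    """Adjusted CDS nucleotide diversity for one gene and stratum."""

    gene: str
    pi_adj: float                 # sum of per-site pi over CDS / CDS length
    pi_per_observed_site: float   # coverage-adjusted: sum of per-site pi / n sites observed
    n_sites_observed: int
    cds_length: int
    stratum: str = "all"
    replicate: int | None = None

    def to_dict(self):
        return dict(self.__dict__)


def _cds_mask(cohort: PhasedCohort, intervals):
    """Indices of cohort variants lying inside any of the 0-based half-open intervals."""
    idx = []
    for j, v in enumerate(cohort.variants):
        p0 = v.pos - 1
        for _, iv in intervals.iterrows():
            if v.chrom == iv["chrom"] and iv["start"] <= p0 < iv["end"]:
                idx.append(j)
                break
    return idx


def adjusted_gene_pi(cohort: PhasedCohort, cds_intervals: pd.DataFrame,
                     stratum="all", label=None, replicate=None) -> list:
    """Per-gene adjusted nucleotide diversity over a cohort stratum.

    ``cds_intervals`` has columns ``gene, chrom, start, end`` (0-based
    half-open; several rows per gene are summed, so splitting an interval
    does not change the result). Missing genotype calls are excluded from a
    site's chromosome count.
    """
    mask = cohort.stratum_mask(stratum)
    if 2 * int(mask.sum()) < 2:
        raise DegenerateInputError("diversity stratum needs >= 2 chromosomes")
    label = label if label is not None else (stratum if isinstance(stratum, str) else "custom")
    results = []
    for gene, ivs in cds_intervals.groupby("gene", sort=False):
        cds_length = int((ivs["end"] - ivs["start"]).sum())
        site_idx = _cds_mask(cohort, ivs)
        pi_sum = 0.0
        n_observed = 0
        for j in site_idx:
            calls = cohort.alleles[mask, j, :]
            observed = calls >= 0
            n = int(observed.sum())
            if n < 2:
                continue
            n_observed += 1
            c_alt = int((calls == 1).sum())
            pi_sum += site_pi(n - c_alt, c_alt)
        if n_observed > cds_length:
            raise ConfigError(f"more observed sites than CDS bases for {gene}")
        results.append(DiversityResult(
            gene=gene,
            pi_adj=pi_sum / cds_length,
            pi_per_observed_site=(pi_sum / n_observed) if n_observed else 0.0,
            n_sites_observed=n_observed,
            cds_length=cds_length,
            stratum=label,
            replicate=replicate,
        ))
    return results


def samples_homozygous_ancestry(tracts: TractSet, chrom, start, end, ancestry) -> np.ndarray:
    """Samples whose both haplotypes are a single ancestry across [start, end).

    This is the ancestry conditioning used before diversity comparisons:
    only individuals inferred homozygous for the target background across the
    gene's span contribute chromosomes.
    """
    code = ANCESTRY_CODES[ancestry] if isinstance(ancestry, str) else int(ancestry)
    if chrom not in tracts.chroms:
        raise ConfigError(f"chromosome {chrom!r} not present in tracts")
    ok = np.ones(tracts.n_samples, dtype=bool)
    for hap_i, (bounds, labels) in enumerate(tracts._data[chrom]):
        lo = np.searchsorted(bounds, start, side="right") - 1
        hi = np.searchsorted(bounds, end - 1, side="right") - 1
        if not np.all(labels[lo:hi + 1] == code):
            ok[hap_i // 2] = False
    return ok


def downsample_strata(cohort: PhasedCohort, targets, k: int = 10, seed: int = 0) -> list:
    """``k`` seeded uniform down-samples of the cohort without replacement.

    ``targets`` is ``{'case': n, 'control': m}`` (either key optional) or an
    integer target applied to the whole cohort. Each replicate keeps the
    cohort's sample order. Replicate membership is byte-reproducible given
    the seed.
    """
    rng = np.random.default_rng(seed)
    if isinstance(targets, int):
        targets = {"all": targets}
    pools = {}
    for stratum, size in targets.items():
        pool = np.flatnonzero(cohort.stratum_mask(stratum))
        if size > len(pool):
            raise ConfigError(
                f"target {size} exceeds stratum {stratum!r} size {len(pool)}")
        pools[stratum] = (pool, size)
    replicates = []
    for _ in range(k):
        keep = []
        for pool, size in pools.values():
            keep.append(rng.choice(pool, size=size, replace=False))
        idx = np.sort(np.concatenate(keep))
        replicates.append(cohort.subset(idx))
    return replicates


def diversity_table(results) -> pd.DataFrame:
    df = pd.DataFrame([r.to_dict() for r in results])
    return df


def replicate_summary(per_replicate_results) -> pd.DataFrame:
    """Across-replicate mean/SD of pi_adj per gene and stratum."""
    df = pd.DataFrame([r.to_dict() for results in per_replicate_results for r in results])
    return (df.groupby(["gene", "stratum"])
              .agg(pi_adj_mean=("pi_adj", "mean"), pi_adj_sd=("pi_adj", "std"),
                   n_replicates=("pi_adj", "size"))
              .reset_index())
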