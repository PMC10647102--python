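"""Synthetic admixed case/control cohort generator.

The generator reproduces the statistical structure that the downstream
analysis assumes about a recently admixed population:

* **Tracts** — a single admixture pulse ``G`` generations ago lays ancestry
  breakpoints along each haplotype as a Poisson process at rate ``G`` per
  Morgan; each resulting segment is independently African with probability
  ``alpha``. Exchangeable segments are sufficient for attribution testing;
  no coalescent realism (drift, background LD) is attempted.
* **Alleles** — each alternate allele copy is drawn conditional on the local
  ancestry of its haplotype: Bernoulli(``f_afr``) on African tracts,
  Bernoulli(``f_eur``) on European tracts, independently across haplotypes
  given the tracts. Rare European-discovered alleles therefore ride European
  tracts, which is the premise the attribution analysis tests.
* **Phenotypes** — disease log-odds are additive in per-variant allele
  counts, ``logit(P(case)) = b0 + sum_v g_v * ln(OR_v)`` (plus an optional
  PRS term), with the intercept solved numerically so the marginal
  prevalence equals ``K``; cases and controls are then ascertained to quota.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import AFR, EUR, PhasedCohort, TractSet
from .config import SimulationConfig
from .errors import ConfigError, CoverageError


def simulate_tracts(config: SimulationConfig, n_individuals=None, rng=None) -> TractSet:
    """Simulate local-ancestry tracts for ``n_individuals`` diploid samples.

    Defaults to ``config.n_cases + config.n_controls`` individuals; pass a
    larger pool when phenotypes will be ascertained afterwards.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples if n_individuals is None else int(n_individuals)
    if n <= 0:
        raise ConfigError("need at least one individual to simulate tracts")
    n_hap = 2 * n
    samples = [f"S{i:06d}" for i in range(n)]
    data = {}
    for chrom, length_bp, length_m in config.chrom_map:
        rate = config.generations * length_m
        counts = rng.poisson(rate, size=n_hap)
        total = int(counts.sum())
        pos = rng.integers(1, length_bp, size=total, dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        entries = []
        for h in range(n_hap):
            bp = np.unique(pos[offsets[h]:offsets[h + 1]])
            bounds = np.concatenate([[0], bp, [length_bp]])
            labels = (rng.random(len(bounds) - 1) >= config.alpha).astype(np.int8)  # 0=AFR w.p. alpha
            entries.append((bounds, labels))
        data[chrom] = entries
    return TractSet(samples, config.chrom_lengths, data, validate=False)


def place_alleles(tracts: TractSet, variants, seed=None, rng=None) -> PhasedCohort:
    """Draw phased alleles for every variant conditional on local ancestry."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = tracts.n_samples
    alleles = np.zeros((n, len(variants), 2), dtype=np.int8)
    for j, v in enumerate(variants):
        try:
            codes = tracts.ancestry_at(v.chrom, v.pos)
        except CoverageError as exc:
            raise CoverageError(f"variant {v.rsid} ({v.key}): {exc}") from exc
        p = np.where(codes == AFR, v.f_afr, v.f_eur)
        alleles[:, j, :] = rng.random((n, 2)) < p
    return PhasedCohort(tracts.samples, list(variants), alleles)


def _solve_intercept(scores, prevalence):
    """Intercept b0 with mean(expit(b0 + scores)) == prevalence."""
    scores = np.asarray(scores, dtype=float)
    if np.allclose(scores, scores[0]):
        return float(logit(prevalence) - scores[0])

    def f(b0):
        return expit(b0 + scores).mean() - prevalence

    lo, hi = -60.0, 60.0
    return float(brentq(f, lo, hi, xtol=1e-12))


def assign_phenotypes(cohort: PhasedCohort, variants, config: SimulationConfig,
                      prs_weights=None, rng=None, ascertain=True):
    """Assign case/control status under the additive log-odds model.

    ``cohort`` is treated as the sampling pool. Returns
    ``(ascertained_cohort, selected_indices)`` where ``selected_indices``
    index into the pool (use them to subset the matching TractSet). With
    ``ascertain=False`` the full pool is returned with its sampled statuses
    (indices are then ``arange(n)``).

    ``prs_weights`` may be a :class:`~admixburden.variants.WeightTable`; any
    weight resolvable against the cohort's variants (by key or rsID) adds
    ``weight * allele count`` to the liability score.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if list(cohort.variants) != list(variants):
        raise ConfigError("variant list does not match the cohort's variants")
    counts = cohort.alt_counts().astype(float)
    beta = np.log([v.or_assumed for v in variants])
    scores = counts @ beta
    if prs_weights is not None:
        w = np.zeros(len(variants))
        for j, v in enumerate(variants):
            if v.key in prs_weights:
                w[j] = prs_weights[v.key]
            elif v.rsid in prs_weights:
                w[j] = prs_weights[v.rsid]
        scores = scores + counts @ w
    b0 = _solve_intercept(scores, config.prevalence)
    p_case = expit(b0 + scores)
    status = rng.random(cohort.n_samples) < p_case
    phenotypes = np.where(status, "case", "control").astype(object)
    if not ascertain:
        return cohort.with_phenotypes(phenotypes), np.arange(cohort.n_samples)

    case_idx = np.flatnonzero(status)
    control_idx = np.flatnonzero(~status)
    if len(case_idx) < config.n_cases or len(control_idx) < config.n_controls:
        raise ConfigError(
            f"infeasible case/control quota: pool of {cohort.n_samples} at prevalence "
            f"{config.prevalence} produced {len(case_idx)} cases / {len(control_idx)} controls, "
            f"need {config.n_cases}/{config.n_controls}; simulate a larger pool"
        )
    sel_cases = case_idx[rng.permutation(len(case_idx))[:config.n_cases]]
    sel_controls = control_idx[rng.permutation(len(control_idx))[:config.n_controls]]
    selected = np.sort(np.concatenate([sel_cases, sel_controls]))
    sub = cohort.subset(selected).with_phenotypes(phenotypes[selected])
    return sub, selected


def simulate_cohort(config: SimulationConfig, variants, prs_weights=None, pool_size=None):
    """End-to-end simulation: tracts -> alleles -> ascertained phenotypes.

    ``pool_size`` controls the pre-ascertainment pool; by default it is sized
    so the case quota is met with high probability under prevalence ``K``
    (at least ``1.5 * n_cases / K`` individuals, and never fewer than the
    requested cohort). Returns ``(cohort, tracts)`` for the ascertained
    samples only.
    """
    rng = np.random.default_rng(config.seed)
    if pool_size is None:
        need = config.n_cases / config.prevalence if config.n_cases else 0
        pool_size = int(max(np.ceil(1.5 * need), config.n_samples, 1))
    if pool_size < config.n_samples:
        raise ConfigError("pool_size smaller than the requested cohort")
    tracts = simulate_tracts(config, n_individuals=pool_size, rng=rng)
    pool = place_alleles(tracts, variants, rng=rng)
    cohort, selected = assign_phenotypes(pool, variants, config, prs_weights=prs_weights, rng=rng)
    return cohort, tracts.subset(selected)


def true_copy_ancestry(cohort: PhasedCohort, tracts: TractSet):
    """Ground-truth ancestry of every alternate-allele copy.

    Returns a list of ``(sample_id, haplotype, variant_key, rsid, ancestry)``
    tuples — the simulator-side truth that attribution must reproduce
    copy-for-copy.
    """
    from .cohort import ANCESTRY_NAMES

    rows = []
    for j, v in enumerate(cohort.variants):
        codes = tracts.ancestry_at(v.chrom, v.pos)
        carriers = np.argwhere(cohort.alleles[:, j, :] == 1)
        for i, hap in carriers:
            rows.append((cohort.samples[i], int(hap), v.key, v.rsid, ANCESTRY_NAMES[codes[i, hap]]))
    return rows


def write_truth_tables(cohort: PhasedCohort, tracts: TractSet, outdir, config=None):
    """Write the full simulation truth to ``outdir``.

    Emits ``cohort.vcf`` (phased GT), ``tracts.bed``, ``phenotypes.tsv``,
    ``truth_copies.tsv`` (per-copy ancestry of every alternate allele) and
    ``truth_ancestry.tsv`` (per-individual tract-length-weighted African
    fraction). All files round-trip losslessly through the package readers.
    """
    import os

    from . import io as io_formats

    os.makedirs(outdir, exist_ok=True)
    seed = None if config is None else config.seed
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "tracts": os.path.join(outdir, "tracts.bed"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "truth_copies": os.path.join(outdir, "truth_copies.tsv"),
        "truth_ancestry": os.path.join(outdir, "truth_ancestry.tsv"),
    }
    chrom_lengths = tracts.chrom_lengths
    io_formats.write_phased_vcf(cohort, paths["vcf"], chrom_lengths=chrom_lengths, seed=seed)
    io_formats.write_tracts(tracts, paths["tracts"], seed=seed)
    io_formats.write_phenotypes(cohort, paths["phenotypes"], seed=seed)

    with open(paths["truth_copies"], "w") as fh:
        fh.write(io_formats.provenance_header(seed))
        fh.write("sample_id\thaplotype\tvariant_key\trsid\tancestry\n")
        for row in true_copy_ancestry(cohort, tracts):
            fh.write("\t".join(str(x) for x in row) + "\n")

    afr = tracts.afr_fraction()
    with open(paths["truth_ancestry"], "w") as fh:
        fh.write(io_formats.provenance_header(seed))
        fh.write("sample_id\tafr_fraction\n")
        for sid, frac in zip(tracts.samples, afr):
            fh.write(f"{sid}\t{frac:.10g}\n")
    return paths
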