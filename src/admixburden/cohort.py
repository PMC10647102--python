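"""In-memory containers: phased genotype cohorts and local-ancestry tract sets.

Coordinate conventions are centralized here: variant positions are 1-based
(VCF style); tracts are half-open 0-based intervals (BED style). A 1-based
position ``p`` lies in interval ``[s, e)`` iff ``s <= p-1 < e``. A variant
falling exactly on a tract boundary therefore belongs to the later-starting
tract — deterministic, no tie.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, CoverageError

AFR = 0
EUR = 1
ANCESTRY_NAMES = ("AFR", "EUR")
ANCESTRY_CODES = {"AFR": AFR, "EUR": EUR}

MISSING = -1  # missing allele call


class TractSet:
    """Local-ancestry tracts for every haplotype of every sample.

    Per haplotype and chromosome the tracts are stored as a breakpoint vector
    ``bounds`` (``[0, b1, ..., L]``) and a label vector of length
    ``len(bounds) - 1`` with codes ``AFR``/``EUR``. Tracts tile each
    chromosome exactly: no gaps, no overlaps.
    """

    def __init__(self, samples, chrom_lengths, data, validate=True):
        self.samples = list(samples)
        self.chrom_lengths = dict(chrom_lengths)
        self._data = data  # chrom -> list over hap index (2*n) of (bounds, labels)
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df, chrom_lengths=None, sample_order=None):
        """Build from long-format intervals.

        ``df`` columns: chrom, start, end, sample_id, haplotype (0/1),
        ancestry ('AFR'/'EUR'). When ``chrom_lengths`` is omitted each
        chromosome's length is taken as the maximum interval end.
        """
        required = {"chrom", "start", "end", "sample_id", "haplotype", "ancestry"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigError(f"tract table missing columns: {sorted(missing)}")
        bad = ~df["ancestry"].isin(ANCESTRY_CODES)
        if bad.any():
            raise ConfigError(
                f"unknown ancestry label {df.loc[bad.idxmax(), 'ancestry']!r} in tract table"
            )
        samples = sample_order if sample_order is not None else list(pd.unique(df["sample_id"]))
        sample_idx = {s: i for i, s in enumerate(samples)}
        chroms = list(pd.unique(df["chrom"]))
        if chrom_lengths is None:
            chrom_lengths = df.groupby("chrom", sort=False)["end"].max().to_dict()
        data = {}
        for chrom in chroms:
            data[chrom] = [None] * (2 * len(samples))
        for (chrom, sid, hap), grp in df.groupby(["chrom", "sample_id", "haplotype"], sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            bounds = np.concatenate([starts, ends[-1:]])
            labels = grp["ancestry"].map(ANCESTRY_CODES).to_numpy(dtype=np.int8)
            if not np.array_equal(starts[1:], ends[:-1]):
                raise ConfigError(
                    f"tracts for sample {sid!r} haplotype {hap} on {chrom} overlap or leave gaps "
                    f"(intervals {list(zip(starts, ends))})"
                )
            data[chrom][2 * sample_idx[sid] + int(hap)] = (bounds, labels)
        return cls(samples, chrom_lengths, data)

    # -- invariants -------------------------------------------------------

    def validate(self):
        """Check that every haplotype's tracts tile each chromosome exactly."""
        n_hap = 2 * len(self.samples)
        for chrom, entries in self._data.items():
            if chrom not in self.chrom_lengths:
                raise ConfigError(f"no length recorded for chromosome {chrom!r}")
            L = self.chrom_lengths[chrom]
            if len(entries) != n_hap:
                raise ConfigError(f"{chrom}: expected {n_hap} haplotypes, got {len(entries)}")
            for hap_i, entry in enumerate(entries):
                if entry is None:
                    sid = self.samples[hap_i // 2]
                    raise ConfigError(f"sample {sid!r} haplotype {hap_i % 2} has no tracts on {chrom}")
                bounds, labels = entry
                if bounds[0] != 0 or bounds[-1] != L:
                    sid = self.samples[hap_i // 2]
                    raise ConfigError(
                        f"tracts for sample {sid!r} haplotype {hap_i % 2} do not tile {chrom} "
                        f"([{bounds[0]}, {bounds[-1]}] vs [0, {L}])"
                    )
                if np.any(np.diff(bounds) <= 0):
                    sid = self.samples[hap_i // 2]
                    raise ConfigError(
                        f"unsorted or zero-length tract for sample {sid!r} haplotype {hap_i % 2} on {chrom}"
                    )
                if len(labels) != len(bounds) - 1:
                    raise ConfigError(f"label/bound mismatch on {chrom}")

    # -- queries ----------------------------------------------------------

    @property
    def n_samples(self):
        return len(self.samples)

    @property
    def chroms(self):
        return list(self._data)

    def ancestry_at(self, chrom, pos):
        """Ancestry code of every haplotype at 1-based position ``pos``.

        Returns an ``(n_samples, 2)`` int8 array of ``AFR``/``EUR`` codes.
        """
        if chrom not in self._data:
            raise CoverageError(f"position {chrom}:{pos} not covered: chromosome absent from tracts")
        p0 = pos - 1
        if not 0 <= p0 < self.chrom_lengths[chrom]:
            raise CoverageError(
                f"position {chrom}:{pos} outside chromosome bounds [1, {self.chrom_lengths[chrom]}]"
            )
        out = np.empty((len(self.samples), 2), dtype=np.int8)
        entries = self._data[chrom]
        for hap_i, (bounds, labels) in enumerate(entries):
            seg = np.searchsorted(bounds, p0, side="right") - 1
            out[hap_i // 2, hap_i % 2] = labels[seg]
        return out

    def afr_fraction(self, chroms=None):
        """Tract-length-weighted African fraction per sample (diploid).

        ``chroms`` restricts the scope to a chromosome subset (the analysis of
        real admixed cohorts often covers only the phased chromosomes).
        """
        scope = list(self._data) if chroms is None else list(chroms)
        for c in scope:
            if c not in self._data:
                raise ConfigError(f"chromosome {c!r} not present in tracts")
        afr_len = np.zeros(len(self.samples))
        total = 0.0
        for chrom in scope:
            total += 2 * self.chrom_lengths[chrom]
            for hap_i, (bounds, labels) in enumerate(self._data[chrom]):
                seg_len = np.diff(bounds)
                afr_len[hap_i // 2] += seg_len[labels == AFR].sum()
        return afr_len / total

    def haplotype_afr_fraction(self):
        """African fraction per haplotype (``2 * n_samples`` values)."""
        afr_len = np.zeros(2 * len(self.samples))
        total = 0.0
        for chrom in self._data:
            total += self.chrom_lengths[chrom]
            for hap_i, (bounds, labels) in enumerate(self._data[chrom]):
                seg_len = np.diff(bounds)
                afr_len[hap_i] += seg_len[labels == AFR].sum()
        return afr_len / total

    def breakpoint_counts(self):
        """Number of ancestry breakpoints per haplotype (segment count - 1 summed over chromosomes)."""
        counts = np.zeros(2 * len(self.samples), dtype=np.int64)
        for chrom in self._data:
            for hap_i, (bounds, _) in enumerate(self._data[chrom]):
                counts[hap_i] += len(bounds) - 2
        return counts

    # -- transforms -------------------------------------------------------

    def subset(self, indices):
        """New TractSet restricted to the given sample indices (order kept)."""
        indices = list(indices)
        samples = [self.samples[i] for i in indices]
        data = {}
        for chrom, entries in self._data.items():
            data[chrom] = []
            for i in indices:
                data[chrom].append(entries[2 * i])
                data[chrom].append(entries[2 * i + 1])
        return TractSet(samples, self.chrom_lengths, data, validate=False)

    def to_dataframe(self):
        rows = []
        for chrom in self._data:
            for hap_i, (bounds, labels) in enumerate(self._data[chrom]):
                sid = self.samples[hap_i // 2]
                hap = hap_i % 2
                for s, e, lab in zip(bounds[:-1], bounds[1:], labels):
                    rows.append((chrom, int(s), int(e), sid, hap, ANCESTRY_NAMES[lab]))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id", "haplotype", "ancestry"])

    def equals(self, other):
        if self.samples != other.samples or set(self._data) != set(other._data):
            return False
        for chrom in self._data:
            for (b1, l1), (b2, l2) in zip(self._data[chrom], other._data[chrom]):
                if not (np.array_equal(b1, b2) and np.array_equal(l1, l2)):
                    return False
        return True


class PhasedCohort:
    """Phased biallelic genotypes for a set of samples, plus phenotypes.

    ``alleles`` has shape ``(n_samples, n_variants, 2)`` with entries 0/1
    (or -1 for a missing call, only possible for cohorts read from VCF).
    """

    def __init__(self, samples, variants, alleles, phenotypes=None):
        self.samples = list(samples)
        self.variants = list(variants)
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.shape != (len(self.samples), len(self.variants), 2):
            raise ConfigError(
                f"allele matrix shape {alleles.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants x 2"
            )
        self.alleles = alleles
        if phenotypes is not None:
            phenotypes = np.asarray(phenotypes, dtype=object)
            if phenotypes.shape != (len(self.samples),):
                raise ConfigError("phenotype vector length does not match sample count")
            bad = ~np.isin(phenotypes, ("case", "control"))
            if bad.any():
                raise ConfigError(f"unknown phenotype label {phenotypes[bad][0]!r}")
        self.phenotypes = phenotypes

    @property
    def n_samples(self):
        return len(self.samples)

    @property
    def n_variants(self):
        return len(self.variants)

    def variant_index(self, key_or_rsid):
        for i, v in enumerate(self.variants):
            if v.key == key_or_rsid or v.rsid == key_or_rsid:
                return i
        raise KeyError(f"variant {key_or_rsid!r} not in cohort")

    def alt_counts(self):
        """Per-sample x per-variant alternate allele counts (missing -> counted as 0)."""
        a = np.where(self.alleles == MISSING, 0, self.alleles)
        return a.sum(axis=2)

    def case_mask(self):
        if self.phenotypes is None:
            raise ConfigError("cohort has no phenotypes")
        return np.asarray(self.phenotypes == "case")

    def stratum_mask(self, stratum):
        """Boolean sample mask for 'case', 'control', 'all', or an explicit mask."""
        if isinstance(stratum, str):
            if stratum == "all":
                return np.ones(self.n_samples, dtype=bool)
            if stratum in ("case", "control"):
                if self.phenotypes is None:
                    raise ConfigError("cohort has no phenotypes")
                return np.asarray(self.phenotypes == stratum)
            raise ConfigError(f"unknown stratum {stratum!r}")
        mask = np.asarray(stratum, dtype=bool)
        if mask.shape != (self.n_samples,):
            raise ConfigError("stratum mask length does not match sample count")
        return mask

    def subset(self, indices, variants=None):
        """New cohort with the given sample indices (and optionally a variant subset)."""
        indices = np.asarray(indices)
        vidx = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        return PhasedCohort(
            [self.samples[i] for i in indices],
            [self.variants[j] for j in vidx],
            self.alleles[indices][:, vidx, :],
            None if self.phenotypes is None else self.phenotypes[indices],
        )

    def with_phenotypes(self, phenotypes):
        return PhasedCohort(self.samples, self.variants, self.alleles, phenotypes)
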