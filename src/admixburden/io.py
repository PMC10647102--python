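"""Readers and writers for every file format the pipeline touches.

Conventions enforced here (strictly — malformed input is rejected, never
coerced):

* VCF 4.2, biallelic records only, phased diploid ``GT`` (``0|1``); an
  unphased separator or ploidy other than 2 is a contract violation named at
  record level. Variant metadata (gene, ancestry frequencies, assumed OR,
  direction) round-trips through INFO fields.
* Tracts as BED-like TSV: 0-based half-open ``chrom, start, end, sample_id,
  haplotype (0/1), ancestry (AFR/EUR)``; intervals must tile each chromosome.
* Variant/weight/phenotype tables as TSV with a mandatory header row;
  ``#`` lines are provenance comments.

Statistics downstream are always computed for the designated ascertained
allele, never re-minored per cohort; a reader warning is emitted when that
allele exceeds frequency 0.5 in any cohort column.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .cohort import ANCESTRY_NAMES, MISSING, PhasedCohort, TractSet
from .errors import FormatError
from .variants import VariantSpec, VariantTable, WeightTable


def provenance_header(seed=None):
    parts = [f"admixburden {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    return "# " + " ".join(parts) + "\n"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_phased_vcf(cohort: PhasedCohort, path, chrom_lengths=None, seed=None):
    """Write a cohort as an uncompressed phased VCF 4.2 file."""
    chrom_lengths = chrom_lengths or {}
    chroms = []
    for v in cohort.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=admixburden_{__version__}\n")
        if seed is not None:
            fh.write(f"##admixburden_seed={seed}\n")
        for chrom in chroms:
            if chrom in chrom_lengths:
                fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        # frequencies/OR as String fields: VCF Float INFO is float32 in common
        # parsers, which would break lossless round-tripping
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=FAFR,Number=1,Type=String,Description="Alt frequency on African background">\n')
        fh.write('##INFO=<ID=FEUR,Number=1,Type=String,Description="Alt frequency on European background">\n')
        fh.write('##INFO=<ID=ORA,Number=1,Type=String,Description="Assumed per-allele odds ratio">\n')
        fh.write('##INFO=<ID=DIR,Number=1,Type=String,Description="risk or protective">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples) + "\n")
        order = sorted(range(cohort.n_variants), key=lambda j: (chroms.index(cohort.variants[j].chrom), cohort.variants[j].pos))
        for j in order:
            v = cohort.variants[j]
            info = (f"GENE={v.gene};FAFR={v.f_afr!r};FEUR={v.f_eur!r};"
                    f"ORA={v.or_assumed!r};DIR={v.direction}")
            gts = []
            for i in range(cohort.n_samples):
                a, b = cohort.alleles[i, j]
                gts.append(("." if a == MISSING else str(a)) + "|" + ("." if b == MISSING else str(b)))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n")


def read_phased_vcf(path) -> PhasedCohort:
    """Read a phased biallelic VCF into a :class:`PhasedCohort`.

    Sample order is preserved. Multi-allelic records, records without GT,
    unphased genotypes and non-diploid calls are rejected with the offending
    record named.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot open VCF: {exc}", path=path) from exc
    samples = list(vf.header.samples)
    variants = []
    columns = []
    with vf:
        for rec in vf:
            where = f"{rec.chrom}:{rec.pos}"
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError("record is not biallelic (exactly one ALT required)", path=path, record=where)
            if "GT" not in rec.format:
                raise FormatError("record has no GT field", path=path, record=where)
            col = np.empty((len(samples), 2), dtype=np.int8)
            for i, sid in enumerate(samples):
                call = rec.samples[sid]
                gt = call["GT"]
                if gt is None or len(gt) != 2:
                    raise FormatError(
                        f"sample {sid} has ploidy != 2", path=path, record=where)
                if not call.phased and not all(a is None for a in gt):
                    raise FormatError(
                        f"sample {sid} genotype is unphased ('/' separator)", path=path, record=where)
                col[i, 0] = MISSING if gt[0] is None else gt[0]
                col[i, 1] = MISSING if gt[1] is None else gt[1]
            def info_get(key, default):
                # undeclared INFO keys make pysam raise rather than miss
                try:
                    return rec.info[key]
                except (KeyError, ValueError):
                    return default

            variants.append(VariantSpec(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                rsid=rec.id or f"{rec.chrom}:{rec.pos}",
                gene=info_get("GENE", ""),
                f_afr=float(info_get("FAFR", 0.0)),
                f_eur=float(info_get("FEUR", 0.0)),
                or_assumed=float(info_get("ORA", 1.0)),
                direction=info_get("DIR", "risk"),
            ))
            columns.append(col)
    if columns:
        alleles = np.stack(columns, axis=1)
    else:
        alleles = np.zeros((len(samples), 0, 2), dtype=np.int8)
    return PhasedCohort(samples, variants, alleles)


# ---------------------------------------------------------------------------
# tracts (BED-like)
# ---------------------------------------------------------------------------

def write_tracts(tracts: TractSet, path, seed=None):
    df = tracts.to_dataframe()
    with open(path, "w") as fh:
        fh.write(provenance_header(seed))
        df.to_csv(fh, sep="\t", index=False)


def read_tracts(path, chrom_lengths=None) -> TractSet:
    """Read a tract BED table; intervals are validated for exact tiling."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read tract table: {exc}", path=path) from exc
    try:
        return TractSet.from_dataframe(df, chrom_lengths=chrom_lengths)
    except Exception as exc:
        raise FormatError(str(exc), path=path) from exc


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(cohort: PhasedCohort, path, seed=None):
    with open(path, "w") as fh:
        fh.write(provenance_header(seed))
        fh.write("sample_id\tstatus\n")
        phen = cohort.phenotypes if cohort.phenotypes is not None else ["NA"] * cohort.n_samples
        for sid, st in zip(cohort.samples, phen):
            fh.write(f"{sid}\t{st}\n")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"sample_id", "status"}
    if not need.issubset(df.columns):
        raise FormatError(f"phenotype table must have columns {sorted(need)}", path=path)
    bad = ~df["status"].isin(["case", "control", "NA"])
    if bad.any():
        raise FormatError(
            f"unknown status {df.loc[bad.idxmax(), 'status']!r}", path=path,
            record=f"line {bad.idxmax() + 2}")
    return df


def attach_phenotypes(cohort: PhasedCohort, path) -> PhasedCohort:
    df = read_phenotypes(path)
    lookup = dict(zip(df["sample_id"], df["status"]))
    missing = [s for s in cohort.samples if s not in lookup]
    if missing:
        raise FormatError(f"phenotype table lacks samples: {missing[:5]}", path=path)
    return cohort.with_phenotypes([lookup[s] for s in cohort.samples])


# ---------------------------------------------------------------------------
# variant / weight tables
# ---------------------------------------------------------------------------

def read_variant_table(path) -> VariantTable:
    """Read a delimited variant annotation table.

    Emits a warning when the ascertained allele exceeds frequency 0.5 in any
    cohort column (it must then be interpreted as a locally major allele, not
    re-minored).
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read variant table: {exc}", path=path) from exc
    try:
        table = VariantTable(df)
    except Exception as exc:
        raise FormatError(str(exc), path=path) from exc
    high = table.high_frequency_alleles()
    if len(high):
        names = high["rsid"].tolist() if "rsid" in high.columns else high.index.tolist()
        warnings.warn(
            f"ascertained allele frequency exceeds 0.5 for {names} in {path}; "
            "statistics are computed for the ascertained allele as-is",
            stacklevel=2,
        )
    return table


def read_weights(path, label=None) -> WeightTable:
    """Read a PRS weight table (columns: ``variant`` or ``rsid``, ``weight``)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read weight table: {exc}", path=path) from exc
    key_col = "variant" if "variant" in df.columns else ("rsid" if "rsid" in df.columns else None)
    if key_col is None or "weight" not in df.columns:
        raise FormatError("weight table needs a 'variant' (or 'rsid') and a 'weight' column", path=path)
    w = pd.to_numeric(df["weight"], errors="coerce")
    if w.isna().any():
        raise FormatError(
            f"non-numeric weight at line {int(w.isna().idxmax()) + 2}", path=path)
    return WeightTable(dict(zip(df[key_col], w.astype(float))), label=label or str(path))


def read_group_map(path) -> dict:
    """Variant -> disease-group mapping; one row per (variant, group) pair.

    A variant listed under several groups belongs to each of them.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"variant", "group"}
    if not need.issubset(df.columns):
        raise FormatError(f"group map must have columns {sorted(need)}", path=path)
    out = {}
    for _, row in df.iterrows():
        out.setdefault(row["variant"], []).append(row["group"])
    return out


# ---------------------------------------------------------------------------
# CDS intervals (GFF3 or simple TSV)
# ---------------------------------------------------------------------------

def read_cds_intervals(path) -> pd.DataFrame:
    """Read CDS intervals for the diversity computation.

    Accepts GFF3 (CDS features; gene symbol taken from a ``gene=`` attribute)
    or a simple TSV with columns ``gene, chrom, start, end`` (0-based
    half-open). Returns a DataFrame in the TSV convention.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or str(path).endswith((".gff", ".gff3")):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
        )
        cds = df[df["type"] == "CDS"].copy()
        if cds.empty:
            raise FormatError("GFF3 contains no CDS features", path=path)
        genes = cds["attributes"].str.extract(r"gene=([^;]+)")[0]
        if genes.isna().any():
            raise FormatError("CDS feature without a gene= attribute", path=path)
        out = pd.DataFrame({
            "gene": genes,
            "chrom": cds["seqid"],
            "start": cds["start"].astype(np.int64) - 1,  # GFF3 is 1-based inclusive
            "end": cds["end"].astype(np.int64),
        })
    else:
        out = pd.read_csv(path, sep="\t", comment="#")
        need = {"gene", "chrom", "start", "end"}
        if not need.issubset(out.columns):
            raise FormatError(f"CDS table must have columns {sorted(need)}", path=path)
    if (out["end"] <= out["start"]).any():
        raise FormatError("CDS interval with end <= start", path=path)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def _write_result_table(df: pd.DataFrame, path, seed=None):
    with open(path, "w") as fh:
        fh.write(provenance_header(seed))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def write_burden_table(rows, path, seed=None):
    """Write per-variant burden rows (list of BurdenRow or DataFrame) as TSV."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame([r.to_dict() for r in rows])
    _write_result_table(df, path, seed=seed)


def write_attribution_table(rows, path, seed=None):
    """Write per-variant ancestry attribution rows as TSV (prop NA when no copies)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame([r.to_dict() for r in rows])
    _write_result_table(df, path, seed=seed)


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
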