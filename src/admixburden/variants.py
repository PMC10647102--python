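"""Variant annotation types and the packaged rare-variant fixtures.

A :class:`VariantSpec` carries everything the simulator and the burden
statistics need about one biallelic variant: its position, the
ancestry-specific frequencies of the ascertained allele, and the per-allele
odds ratio with its direction of effect.

The packaged fixtures transcribe the printed summary tables of the Crohn's
disease rare-variant study this package operationalizes: 25 coding variants
at 14 IBD genes with African/European frequencies, odds ratios, variance
explained and excess-case burden, plus 6 low-EP-score variants found in
African Americans. The printed tables carry no genomic coordinates, so
positions attached to the 25-variant set for simulation purposes are
synthetic (gene-level chromosome placement only).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

RISK = "risk"
PROTECTIVE = "protective"

#: Chromosome of each fixture gene (the 25 variants span 10 autosomes).
GENE_CHROM = {
    "PTAFR": "chr1", "IL23R": "chr1",
    "HGFAC": "chr4", "SLC39A8": "chr4", "PDLIM5": "chr4",
    "TAGAP": "chr6",
    "DOK2": "chr8",
    "CARD9": "chr9",
    "RELA": "chr11", "IL10RA": "chr11",
    "NOD2": "chr16",
    "CCR7": "chr17",
    "TYK2": "chr19",
    "SDF2L1": "chr22",
}


@dataclass(frozen=True)
class VariantSpec:
    """One annotated biallelic variant."""

    chrom: str
    pos: int  # 1-based physical position
    ref: str
    alt: str
    rsid: str
    gene: str
    f_afr: float
    f_eur: float
    or_assumed: float
    direction: str = RISK

    def __post_init__(self):
        for name, f in (("f_afr", self.f_afr), ("f_eur", self.f_eur)):
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1] for {self.rsid}, got {f}")
        if not self.or_assumed > 0:
            raise ConfigError(f"or_assumed must be > 0 for {self.rsid}")
        if self.pos < 1:
            raise ConfigError(f"pos must be >= 1 for {self.rsid}")
        if self.direction not in (RISK, PROTECTIVE):
            raise ConfigError(f"direction must be 'risk' or 'protective' for {self.rsid}")

    @property
    def key(self):
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class VariantTable:
    """An ordered variant annotation table (thin wrapper over a DataFrame).

    Guarantees unique variant keys and frequency columns within [0, 1]. The
    designated ascertained allele is held fixed across cohorts: statistics are
    never re-oriented to the locally minor allele, so a frequency above 0.5 in
    some cohort is legal but worth a warning (the classic trap being an allele
    that is minor in Europeans but major in Africans).
    """

    #: columns treated as cohort frequencies when present
    FREQ_COLUMNS = (
        "aa_maf", "eu_maf", "af_case", "af_control", "af_gnomad_afr",
        "f_afr", "f_eur",
    )

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self):
        df = self.df
        if {"chrom", "pos", "ref", "alt"}.issubset(df.columns):
            keys = df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
        elif "rsid" in df.columns:
            keys = df["rsid"]
        else:
            raise ConfigError("variant table needs chrom/pos/ref/alt or rsid columns")
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ConfigError(f"duplicate variant key in table: {dup}")
        for col in self.FREQ_COLUMNS:
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="coerce")
                bad = vals.notna() & ((vals < 0) | (vals > 1))
                if bad.any():
                    row = df.loc[bad.idxmax()]
                    raise ConfigError(
                        f"frequency outside [0, 1] in column {col!r} at {row.get('rsid', bad.idxmax())}"
                    )

    def __len__(self):
        return len(self.df)

    def high_frequency_alleles(self, threshold=0.5):
        """Rows where the ascertained allele exceeds ``threshold`` in any cohort."""
        df = self.df
        mask = np.zeros(len(df), dtype=bool)
        for col in self.FREQ_COLUMNS:
            if col in df.columns:
                mask |= pd.to_numeric(df[col], errors="coerce").to_numpy() > threshold
        return df[mask]


class WeightTable:
    """Liability-scale PRS weights, keyed by variant identifier."""

    def __init__(self, weights: dict, label: str = ""):
        for key, w in weights.items():
            if not np.isfinite(w):
                raise ConfigError(f"non-finite weight for {key} in weight set {label!r}")
        self.weights = dict(weights)
        self.label = label

    def __len__(self):
        return len(self.weights)

    def __getitem__(self, key):
        return self.weights[key]

    def __contains__(self, key):
        return key in self.weights

    def items(self):
        return self.weights.items()


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name):
    return importlib.resources.files("admixburden.data").joinpath(name)


def load_cd_variant_table() -> VariantTable:
    """The 25 rare Crohn's disease coding variants (19 risk, 6 protective)."""
    with importlib.resources.as_file(_data_path("cd_rare_variants.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return VariantTable(df)


def load_ep_variant_table() -> VariantTable:
    """The 6 low-EP-score variants observed in African Americans."""
    with importlib.resources.as_file(_data_path("ep_pathogenic_range_variants.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return VariantTable(df)


def load_worked_example() -> dict:
    """The printed excess-case worked scenario (p=0.01, OR=1.3 -> 5 excess)."""
    import json

    with importlib.resources.as_file(_data_path("worked_example.json")) as p:
        with open(p) as fh:
            return json.load(fh)


def cd_variant_specs(or_column="eu_or", chrom_map=None) -> list:
    """Build simulation-ready :class:`VariantSpec` objects from the CD fixture.

    The printed table has no coordinates, so positions are synthetic: variants
    are placed on their gene's chromosome at deterministic, well-separated
    positions. ``or_column`` selects which printed odds ratio drives the
    disease model (``eu_or`` by default; rows whose selected OR is missing get
    OR 1.0, i.e. no effect). Frequencies are the printed gnomAD African /
    Non-Finnish European values.
    """
    table = load_cd_variant_table().df
    lengths = None
    if chrom_map is not None:
        lengths = {name: bp for name, bp, _ in chrom_map}
    specs = []
    gene_seen = {}
    for _, row in table.iterrows():
        gene = row["gene"]
        chrom = GENE_CHROM[gene]
        idx = gene_seen.get(gene, 0)
        gene_seen[gene] = idx + 1
        # deterministic synthetic placement: genes 2 Mb apart, variants 10 kb apart
        gene_rank = sorted(GENE_CHROM).index(gene)
        pos = 1_000_000 + gene_rank * 2_000_000 + idx * 10_000
        if lengths is not None and pos > lengths.get(chrom, np.inf):
            raise ConfigError(f"synthetic position {pos} exceeds {chrom} length")
        or_val = row[or_column]
        or_assumed = float(or_val) if pd.notna(or_val) else 1.0
        specs.append(
            VariantSpec(
                chrom=chrom, pos=pos, ref="A", alt="G",
                rsid=row["rsid"], gene=gene,
                f_afr=float(row["aa_maf"]), f_eur=float(row["eu_maf"]),
                or_assumed=or_assumed, direction=row["direction"],
            )
        )
    return specs
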