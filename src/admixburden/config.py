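"""Simulation configuration for the synthetic admixed cohort generator.

The generator emulates a two-way admixed population (African/European, as in
African Americans) under a single pulse of admixture ``generations`` ago.
Ancestry switch points accumulate along the genetic map as a Poisson process
at rate ``generations`` per Morgan, and each resulting segment is African
with probability ``alpha``. Disease status follows a logistic (additive in
log-odds) model on per-variant allele counts with marginal prevalence
``prevalence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigError

#: Approximate physical lengths of the 22 human autosomes in Mb (GRCh38 scale),
#: used with a uniform 1 cM/Mb genetic map unless a custom map is supplied.
_AUTOSOME_MB = {
    "chr1": 249, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 182,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51,
}


def default_chrom_map(chroms=None):
    """Chromosome map as a list of ``(name, length_bp, length_morgans)``.

    Defaults to the 22 autosomes with a uniform 1 cM/Mb recombination rate.
    ``chroms`` restricts the map to a subset of chromosome names.
    """
    names = list(_AUTOSOME_MB) if chroms is None else list(chroms)
    out = []
    for name in names:
        if name not in _AUTOSOME_MB:
            raise ConfigError(f"unknown chromosome {name!r} in default map")
        bp = _AUTOSOME_MB[name] * 1_000_000
        out.append((name, bp, bp / 1e8))  # 1 cM/Mb -> Morgans = bp / 1e8
    return out


@dataclass
class SimulationConfig:
    """Parameters of one synthetic-cohort simulation.

    Parameters
    ----------
    n_cases, n_controls
        Ascertainment quotas for the final case/control cohort.
    alpha
        Global African ancestry proportion in [0, 1] (African Americans are
        typically ~0.75-0.80 African).
    generations
        Age of the admixture pulse in generations (G); the expected number of
        ancestry breakpoints per haplotype is G x genetic map length.
    prevalence
        Marginal disease prevalence K used by the liability model.
    chrom_map
        List of ``(chrom, length_bp, length_morgans)`` tuples.
    seed
        Integer RNG seed; all outputs are byte-reproducible given the seed.
    """

    n_cases: int
    n_controls: int
    alpha: float = 0.8
    generations: int = 12
    prevalence: float = 0.01
    chrom_map: list = field(default_factory=default_chrom_map)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.generations < 1:
            raise ConfigError(f"generations must be >= 1, got {self.generations}")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError("n_cases and n_controls must be non-negative")
        if not self.chrom_map:
            raise ConfigError("chrom_map must contain at least one chromosome")
        for entry in self.chrom_map:
            name, bp, morgans = entry
            if bp <= 0 or morgans <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length")

    @property
    def n_samples(self):
        return self.n_cases + self.n_controls

    @property
    def total_morgans(self):
        return sum(m for _, _, m in self.chrom_map)

    @property
    def chrom_lengths(self):
        return {name: bp for name, bp, _ in self.chrom_map}

    def to_dict(self):
        d = asdict(self)
        d["chrom_map"] = [list(t) for t in self.chrom_map]
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "chrom_map" in d and d["chrom_map"] is not None:
            d["chrom_map"] = [tuple(t) for t in d["chrom_map"]]
        else:
            d.pop("chrom_map", None)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
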