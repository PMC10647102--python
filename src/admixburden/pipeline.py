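"""Pipeline orchestration: simulate -> attribute -> burden -> prs -> diversity.

Each stage reads and writes plain TSV/VCF/BED files so it is independently
testable and replaceable; a JSON run manifest records the config hash, seed,
input digests and per-stage output digests, making end-to-end determinism
checkable by comparing manifests.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import io as io_formats
from .attribution import ancestry_vs_count, attribute_copies, global_fractions
from .burden import build_burden_table
from .config import SimulationConfig, default_chrom_map
from .errors import AdmixBurdenError
from .prs import prs_score, prs_vs_ancestry
from .simulate import simulate_cohort, write_truth_tables
from .variants import cd_variant_specs


class StageError(AdmixBurdenError):
    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _count_rows(path):
    with open(path) as fh:
        return sum(1 for line in fh if line.strip() and not line.startswith("#"))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    inputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def record(self, stage, outputs):
        self.stages[stage] = {
            os.path.basename(p): {"sha256": _sha256(p), "rows": _count_rows(p)}
            for p in outputs
        }

    def to_dict(self):
        return {"config_hash": self.config_hash, "seed": self.seed,
                "version": self.version, "inputs": self.inputs, "stages": self.stages}

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


DEFAULT_STAGES = ("simulate", "attribute", "burden", "prs", "diversity")


def run_pipeline(config: dict, outdir, stages=None) -> RunManifest:
    """Run the requested stages in dependency order under ``outdir``.

    ``config`` is a plain dict (see the README for the YAML layout) with a
    ``simulation`` section plus optional ``variants`` / ``prs_weights`` /
    ``cds`` entries. Stage failures raise :class:`StageError` naming the
    stage; outputs of completed stages are left on disk.
    """
    os.makedirs(outdir, exist_ok=True)
    stages = list(stages) if stages is not None else [
        s for s in DEFAULT_STAGES
        if s not in ("prs", "diversity")
        or (s == "prs" and config.get("prs_weights"))
        or (s == "diversity" and config.get("cds"))
    ]
    sim_cfg = dict(config.get("simulation", {}))
    chroms = sim_cfg.pop("chroms", None)
    if "chrom_map" not in sim_cfg and chroms is not None:
        sim_cfg["chrom_map"] = default_chrom_map(chroms)
    cfg = SimulationConfig.from_dict(sim_cfg)
    canon = json.dumps({**config, "simulation": cfg.to_dict()}, sort_keys=True, default=str)
    manifest = RunManifest(hashlib.sha256(canon.encode()).hexdigest(), cfg.seed)

    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "tracts": os.path.join(outdir, "tracts.bed"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
    }

    or_col = config.get("or_column", "eu_or")
    for stage in stages:
        try:
            if stage == "simulate":
                variants_path = config.get("variants")
                if variants_path:
                    manifest.inputs[variants_path] = _sha256(variants_path)
                    specs = _specs_from_file(variants_path)
                else:
                    specs = cd_variant_specs(or_column=or_col, chrom_map=cfg.chrom_map)
                specs = [v for v in specs if v.chrom in cfg.chrom_lengths]
                cohort, tracts = simulate_cohort(cfg, specs,
                                                 pool_size=config.get("pool_size"))
                out = write_truth_tables(cohort, tracts, outdir, config=cfg)
                manifest.record("simulate", out.values())
            elif stage == "attribute":
                cohort, tracts = _load_cohort(paths, manifest)
                rows = attribute_copies(cohort, tracts)
                att_path = os.path.join(outdir, "attribution.tsv")
                io_formats.write_attribution_table(rows, att_path, seed=cfg.seed)
                summary = global_fractions(tracts, cohort=cohort,
                                           chroms=config.get("ancestry_chroms"))
                anc_path = os.path.join(outdir, "ancestry.tsv")
                with open(anc_path, "w") as fh:
                    fh.write(io_formats.provenance_header(cfg.seed))
                    summary.to_dataframe().to_csv(fh, sep="\t", index=False, float_format="%.10g")
                reg = ancestry_vs_count(summary, phenotypes=cohort.phenotypes)
                reg_path = os.path.join(outdir, "ancestry_regression.json")
                with open(reg_path, "w") as fh:
                    json.dump(reg, fh, indent=2, sort_keys=True)
                    fh.write("\n")
                manifest.record("attribute", [att_path, anc_path, reg_path])
            elif stage == "burden":
                cohort, _ = _load_cohort(paths, manifest, need_tracts=False)
                rows = build_burden_table(cohort,
                                          prevalence=config.get("prevalence", cfg.prevalence))
                bur_path = os.path.join(outdir, "burden.tsv")
                io_formats.write_burden_table(rows, bur_path, seed=cfg.seed)
                manifest.record("burden", [bur_path])
            elif stage == "prs":
                cohort, tracts = _load_cohort(paths, manifest)
                outs = []
                results = []
                for wpath in config.get("prs_weights", []):
                    manifest.inputs[wpath] = _sha256(wpath)
                    results.append(prs_score(cohort, io_formats.read_weights(wpath)))
                if not results:
                    raise StageError("prs", "no prs_weights configured")
                afr = tracts.afr_fraction(chroms=config.get("ancestry_chroms"))
                corr = prs_vs_ancestry(results, afr, phenotypes=cohort.phenotypes)
                prs_path = os.path.join(outdir, "prs_scores.tsv")
                with open(prs_path, "w") as fh:
                    fh.write(io_formats.provenance_header(cfg.seed))
                    wide = pd.concat(
                        [r.to_dataframe().set_index("sample_id")["score"].rename(r.label)
                         for r in results], axis=1).reset_index()
                    wide.to_csv(fh, sep="\t", index=False, float_format="%.10g")
                corr_path = os.path.join(outdir, "prs_ancestry_corr.tsv")
                with open(corr_path, "w") as fh:
                    fh.write(io_formats.provenance_header(cfg.seed))
                    corr.to_csv(fh, sep="\t", index=False, float_format="%.10g")
                outs += [prs_path, corr_path]
                manifest.record("prs", outs)
            elif stage == "diversity":
                from .diversity import adjusted_gene_pi, diversity_table

                cohort, _ = _load_cohort(paths, manifest, need_tracts=False)
                cds_path = config.get("cds")
                if not cds_path:
                    raise StageError("diversity", "no cds intervals configured")
                manifest.inputs[cds_path] = _sha256(cds_path)
                cds = io_formats.read_cds_intervals(cds_path)
                results = []
                strata = ("case", "control") if cohort.phenotypes is not None else ("all",)
                for stratum in strata:
                    results += adjusted_gene_pi(cohort, cds, stratum=stratum)
                div_path = os.path.join(outdir, "diversity.tsv")
                with open(div_path, "w") as fh:
                    fh.write(io_formats.provenance_header(cfg.seed))
                    diversity_table(results).to_csv(fh, sep="\t", index=False,
                                                    float_format="%.10g", na_rep="NA")
                manifest.record("diversity", [div_path])
            else:
                raise StageError(stage, "unknown stage")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    manifest.write(os.path.join(outdir, "manifest.json"))
    return manifest


def _specs_from_file(path):
    from .variants import VariantSpec

    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"chrom", "pos", "ref", "alt", "rsid", "gene", "f_afr", "f_eur", "or_assumed", "direction"}
    missing = need - set(df.columns)
    if missing:
        raise AdmixBurdenError(f"variant spec table missing columns {sorted(missing)}")
    return [VariantSpec(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
                        rsid=r.rsid, gene=r.gene, f_afr=float(r.f_afr),
                        f_eur=float(r.f_eur), or_assumed=float(r.or_assumed),
                        direction=r.direction)
            for r in df.itertuples()]


def _load_cohort(paths, manifest, need_tracts=True):
    for key in ("vcf", "phenotypes") + (("tracts",) if need_tracts else ()):
        if not os.path.exists(paths[key]):
            raise AdmixBurdenError(f"required input {paths[key]} not found (run 'simulate' first)")
        # keyed by basename so manifests are comparable across output dirs
        manifest.inputs.setdefault(os.path.basename(paths[key]), _sha256(paths[key]))
    cohort = io_formats.read_phased_vcf(paths["vcf"])
    cohort = io_formats.attach_phenotypes(cohort, paths["phenotypes"])
    tracts = io_formats.read_tracts(paths["tracts"]) if need_tracts else None
    return cohort, tracts


def make_fixtures(outdir):
    """Write the packaged printed-table fixtures to ``outdir``.

    Emits the 25-variant CD summary table, the 6-variant EP-score table and
    the excess-case worked-example scenario, all validated by the package
    readers on the way out.
    """
    import importlib.resources
    import shutil

    os.makedirs(outdir, exist_ok=True)
    out = {}
    for name in ("cd_rare_variants.tsv", "ep_pathogenic_range_variants.tsv", "worked_example.json"):
        src = importlib.resources.files("admixburden.data").joinpath(name)
        dst = os.path.join(outdir, name)
        with importlib.resources.as_file(src) as p:
            shutil.copy(p, dst)
        out[name] = dst
    # validate through the readers
    io_formats.read_variant_table(out["cd_rare_variants.tsv"])
    io_formats.read_variant_table(out["ep_pathogenic_range_variants.tsv"])
    with open(out["worked_example.json"]) as fh:
        json.load(fh)
    return out
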