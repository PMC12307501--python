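"""End-to-end pipeline: impute -> aging proteins -> trajectories -> clock ->
modulators -> optional GMT enrichment, from a single config.

Every stage's outputs are written as TSV/JSON into the output directory and a
machine-readable ``report.json`` summarizes counts, the signature,
calibration parameters, MAE and class counts. The report is byte-identical
for identical config + seed. One global seed fans out to per-stage seeds by
stable hashing of the stage name, so changing one stage's settings does not
perturb another stage's randomness.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clock as clock_mod
from . import differential as diff_mod
from . import enrichment as enrich_mod
from . import modulators as mod_mod
from . import trajectories as traj_mod
from .core_data import (
    AbundanceTable,
    CohortMetadata,
    ImputationConfig,
    impute_missing,
    read_abundance_table,
    read_metadata,
    write_abundance_table,
    zscore_per_protein,
)
from .errors import ConfigurationError, ValidationError

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed and the stage name."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Paths and per-stage settings for a full run."""

    abundance_path: str
    metadata_path: str
    out_dir: str
    gmt_path: str | None = None
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    span: float = 0.75
    loess_degree: int = 2
    grid_size: int = 50
    k_clusters: int = 7
    linkage: str = "complete"
    cluster_on: str = "fitted"
    alpha_fdr: float = 0.05
    clock: clock_mod.ClockConfig = field(default_factory=clock_mod.ClockConfig)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha_fdr < 1:
            raise ConfigurationError("alpha_fdr must lie in (0, 1)")
        if self.cluster_on not in ("fitted", "raw"):
            raise ConfigurationError("cluster_on must be 'fitted' or 'raw'")

    @classmethod
    def from_yaml(cls, path, out_dir=None, seed=None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if out_dir is not None:
            raw["out_dir"] = str(out_dir)
        if seed is not None:
            raw["seed"] = int(seed)
        imput = ImputationConfig(**raw.pop("imputation", {}))
        clock_cfg = clock_mod.ClockConfig(**raw.pop("clock", {}))
        return cls(imputation=imput, clock=clock_cfg, **raw)

    def validate_paths(self) -> None:
        for label, p in (("abundance", self.abundance_path),
                         ("metadata", self.metadata_path),
                         ("gmt", self.gmt_path)):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{label} file not found: {p}")


def _fanned(cfg: PipelineConfig) -> PipelineConfig:
    """Copy of cfg with per-stage seeds derived from the global seed."""
    imput = dataclasses.replace(cfg.imputation, seed=stage_seed(cfg.seed, "impute"))
    clk = dataclasses.replace(cfg.clock, seed=stage_seed(cfg.seed, "clock"))
    return dataclasses.replace(cfg, imputation=imput, clock=clk)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and write all outputs; returns the report."""
    cfg.validate_paths()
    cfg = _fanned(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ahaging")
    root.addHandler(handler)
    try:
        report: dict = {"seed": cfg.seed, "alpha_fdr": cfg.alpha_fdr}
        stage = "read"
        table = read_abundance_table(cfg.abundance_path)
        meta = read_metadata(cfg.metadata_path)
        meta.check_matches(table)
        report["n_proteins_input"] = len(table.protein_ids)
        report["n_samples"] = len(table.sample_ids)

        stage = "impute"
        logger.info("imputation config: %s", cfg.imputation)
        imputed = impute_missing(table, cfg.imputation)
        write_abundance_table(imputed, out / "abundance_imputed.tsv")
        dropped = sorted(set(table.protein_ids) - set(imputed.protein_ids))
        report["n_proteins_after_missing_filter"] = len(imputed.protein_ids)
        report["dropped_proteins"] = dropped

        stage = "aging_proteins"
        records = diff_mod.differential_analysis(imputed, meta, alpha=cfg.alpha_fdr)
        records.to_csv(out / "aging_proteins.tsv", sep="\t")
        aps = records.index[records["is_ap"]].tolist()
        ap_directions = records.loc[aps, "direction"].to_dict()
        up = [p for p in aps if ap_directions[p] == "up"]
        down = [p for p in aps if ap_directions[p] == "down"]
        report["ap_counts"] = {"total": len(aps), "up": len(up), "down": len(down)}
        with open(out / "ap_summary.json", "w") as fh:
            json.dump({"up": sorted(up), "down": sorted(down)}, fh, indent=2, sort_keys=True)

        stage = "trajectories"
        z = zscore_per_protein(imputed)
        fitted = traj_mod.fit_trajectories(z, meta, span=cfg.span,
                                           degree=cfg.loess_degree,
                                           grid_size=cfg.grid_size)
        profiles = fitted if cfg.cluster_on == "fitted" else z.data
        clusters = traj_mod.cluster_trajectories(profiles, k=cfg.k_clusters,
                                                 linkage=cfg.linkage)
        ap_universe = set(z.data.index)
        clusters = traj_mod.cluster_ap_enrichment(
            clusters, [p for p in aps if p in ap_universe], ap_universe,
            alpha=cfg.alpha_fdr)
        traj_out = fitted.copy()
        traj_out.insert(0, "cluster", clusters.assignments)
        traj_out.to_csv(out / "trajectory_clusters.tsv", sep="\t")
        clusters.table.to_csv(out / "cluster_enrichment.tsv", sep="\t")
        report["clusters"] = {
            str(c): {"size": int(r["size"]), "ap_count": int(r["ap_count"]),
                     "padj": float(r["padj"]), "retained": bool(r["retained"])}
            for c, r in clusters.table.iterrows()
        }

        stage = "clock"
        if not aps:
            raise ValidationError("no aging proteins found; cannot fit the clock")
        result = clock_mod.fit_aging_clock(imputed, meta, aps, cfg.clock)
        result.signature_model.to_json(out / "clock_model.json")
        result.assessments.to_csv(out / "age_assessments.tsv", sep="\t")
        auc = pd.Series(
            {p: clock_mod.protein_auc(imputed.data.loc[p], meta.group) for p in aps},
            name="auc",
        )
        auc.rename_axis("protein_id").to_csv(out / "auc.tsv", sep="\t")
        class_counts = result.assessments["ager_class"].value_counts().to_dict()
        report["clock"] = {
            "signature": sorted(result.signature_model.signature),
            "signature_size": len(result.signature_model.signature),
            "frequencies": {k: int(v) for k, v in result.frequencies.items()},
            "calibration_intercept": result.full_model.calibration_intercept,
            "calibration_slope": result.full_model.calibration_slope,
            "mae_train": result.mae_train,
            "mae_test": result.mae_test,
            "test_r_signature": result.test_r,
            "ager_class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
        }

        stage = "modulators"
        ap_table = imputed.subset_proteins(aps)
        delta = result.assessments["delta_age"]
        classes = result.assessments["ager_class"]
        try:
            mods = mod_mod.modulator_records(ap_table, meta, delta, classes,
                                             alpha=cfg.alpha_fdr)
        except ValidationError as exc:
            logger.warning("modulator stage degenerate (%s); Δage model only", exc)
            mods = mod_mod.delta_age_modulators(ap_table, meta, delta,
                                                alpha=cfg.alpha_fdr)
        mods.to_csv(out / "modulators.tsv", sep="\t")
        summary = {
            "n_modulators": int(mods["is_modulator"].sum()),
            "positive": int(((mods["sign"] == "positive") & mods["is_modulator"]).sum()),
            "negative": int(((mods["sign"] == "negative") & mods["is_modulator"]).sum()),
        }
        if "label" in mods.columns:
            summary["decelerating"] = int((mods["label"] == "decelerating").sum())
            summary["accelerating"] = int((mods["label"] == "accelerating").sum())
        with open(out / "modulator_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        report["modulators"] = summary

        stage = "enrichment"
        if cfg.gmt_path:
            collection = enrich_mod.read_gmt(cfg.gmt_path)
            table_enr = enrich_mod.enrich(aps, collection, imputed.protein_ids,
                                          alpha=cfg.alpha_fdr)
            table_enr.to_csv(out / "enrichment.tsv", sep="\t")
            report["enrichment"] = {
                "n_sets": len(table_enr),
                "n_enriched": int(table_enr["enriched"].sum()),
            }

        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
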