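"""End-to-end orchestration: simulate (or load) -> scan -> score -> report.

``run_pipeline`` executes the full analysis on a configuration and writes a
report bundle of plain-text data products: a cohort-summary table, per-
phenotype scan results with significance tiers, variance-decomposition
tables, continuum and score-histogram data, natural-history curves, an
outlier/misclassification report, and a machine-readable run log with the
seeds and sample counts actually used.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (PhenotypeTable, compute_pcs, read_genotypes,
                     read_phenotypes, summarize_cohort, summary_to_frame,
                     write_genotypes, write_phenotypes, write_variant_metadata)
from .nathist import behaviour_prevalence, km_estimate, logrank_test
from .scan import ScanConfig, flag_significance, results_to_frame, run_scan
from .scores import (build_score_weights, continuum_summary, enrichment_test,
                     estimate_effect_panel, exclude_loci, flag_outliers,
                     score_histogram, score_samples)
from .simulate import SimulationConfig, emulate_rephenotyping, simulate_cohort
from .variance import power_table, variance_decomposition


@dataclass
class PipelineConfig:
    out_dir: str = "ibdpheno_run"
    seed: int = 0
    simulate: dict | None = field(default_factory=dict)
    genotypes: str | None = None      # real-input mode paths
    phenotypes: str | None = None
    variant_metadata: str | None = None
    n_pcs: int = 5
    scan_phenotypes: tuple = ("location", "behaviour", "extent", "age")
    score_contrast: str = "CD_vs_UC"
    outlier_lo: float = -2.0
    outlier_hi: float = 2.0
    rephenotype_sensitivity: float = 0.85
    rephenotype_false_doubt: float = 0.08
    write_cohort: bool = False

    def __post_init__(self):
        if self.simulate is not None and self.genotypes is not None:
            raise ValueError("exactly one of simulate / real-input must be set")
        if not self.outlier_lo < 0 < self.outlier_hi:
            raise ValueError("outlier thresholds must satisfy lo < 0 < hi")


_KNOWN_KEYS = set(PipelineConfig.__dataclass_fields__)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, fill defaults, and report all schema errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors = [f"unknown key: {k}" for k in raw if k not in _KNOWN_KEYS]
    if "seed" not in raw:
        raw["seed"] = 0
    sim = raw.get("simulate")
    if sim:
        bad = [k for k in sim if k not in SimulationConfig.__dataclass_fields__]
        errors += [f"unknown simulate key: {k}" for k in bad]
    if errors:
        raise ValueError("config errors:\n  " + "\n  ".join(errors))
    return PipelineConfig(**raw)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the report-bundle paths keyed by artifact."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "version": __version__, "stages": {}}
    artifacts: dict = {}
    try:
        # --- cohort ---------------------------------------------------
        if cfg.simulate is not None:
            sim_cfg = SimulationConfig(**{**cfg.simulate, "seed": cfg.seed})
            G, P, truth = simulate_cohort(sim_cfg)
            log["stages"]["simulate"] = {"n": sim_cfg.n_samples,
                                         "n_variants": G.n_variants}
        else:
            G = read_genotypes(cfg.genotypes,
                               dialect="vcf" if str(cfg.genotypes).endswith(
                                   (".vcf", ".vcf.gz")) else "dosage_tsv",
                               metadata=cfg.variant_metadata)
            P = read_phenotypes(cfg.phenotypes, strict=False)
            truth = None
        if cfg.write_cohort:
            write_genotypes(G, out / "genotypes.tsv")
            write_variant_metadata(G, out / "variants.tsv")
            write_phenotypes(P, out / "phenotypes.tsv")
        pcs = compute_pcs(G, k=cfg.n_pcs)

        # --- cohort summary -------------------------------------------
        summary_to_frame(summarize_cohort(P)).to_csv(
            out / "cohort_summary.tsv", sep="\t", index=False)
        artifacts["cohort_summary"] = out / "cohort_summary.tsv"

        # --- scans -----------------------------------------------------
        for pheno in cfg.scan_phenotypes:
            sc = ScanConfig(phenotype=pheno, n_pcs=cfg.n_pcs)
            results = run_scan(G, P, sc, pcs=pcs)
            frame = results_to_frame(results)
            tiers = flag_significance(results, sc)
            frame = frame.merge(tiers[["variant", "tier"]], on="variant")
            frame.to_csv(out / f"scan_{pheno}.tsv", sep="\t", index=False)
            artifacts[f"scan_{pheno}"] = out / f"scan_{pheno}.tsv"
            log["stages"][f"scan_{pheno}"] = {
                "n_variants": len(results),
                "n_failed": int(sum(not r.converged for r in results))}

        # --- risk scores ----------------------------------------------
        panel = estimate_effect_panel(G, P.df["diagnosis"].where(
            P.df["diagnosis"].isin(["CD", "UC"])).to_numpy(object), pcs)
        panel.to_tsv(out / "score_weights.tsv")
        w = build_score_weights(panel, cfg.score_contrast)
        scores = score_samples(G, w, cfg.score_contrast, center=True)
        labels = _continuum_labels(P)
        continuum_summary(scores, labels).to_csv(
            out / "continuum.tsv", sep="\t", index=False)
        score_histogram(scores, P.df["diagnosis"].to_numpy(object)).to_csv(
            out / "score_histogram.tsv", sep="\t", index=False)
        artifacts["continuum"] = out / "continuum.tsv"
        artifacts["score_histogram"] = out / "score_histogram.tsv"
        pd.DataFrame({"sample_id": scores.samples, "raw": scores.raw,
                      "standardized": scores.standardized}).to_csv(
            out / "scores.tsv", sep="\t", index=False)

        # --- outliers / misdiagnosis ----------------------------------
        outliers = flag_outliers(scores, P, lo=cfg.outlier_lo,
                                 hi=cfg.outlier_hi, seed=cfg.seed)
        outliers.to_csv(out / "outliers.tsv", sep="\t", index=False)
        artifacts["outliers"] = out / "outliers.tsv"
        if truth is not None and truth.per_sample["swapped_label"].any():
            P_rev = emulate_rephenotyping(
                P, truth, sensitivity=cfg.rephenotype_sensitivity,
                false_doubt_rate=cfg.rephenotype_false_doubt, seed=cfg.seed)
            enr = enrichment_test(outliers, P_rev)
            (out / "enrichment.json").write_text(json.dumps(enr, indent=2))
            artifacts["enrichment"] = out / "enrichment.json"
            log["stages"]["enrichment"] = enr

        # --- variance decomposition -----------------------------------
        try:
            vt = variance_decomposition(P, G, outcome="location",
                                        score=scores.raw)
            vt.to_csv(out / "variance_location.tsv", sep="\t", index=False)
            artifacts["variance_location"] = out / "variance_location.tsv"
        except ValueError as exc:
            log["stages"]["variance_location"] = {"skipped": str(exc)}

        # --- natural history ------------------------------------------
        cd = P.df["diagnosis"] == "CD"
        t = P.df["surgery_time_years"].to_numpy(float)
        e = P.df["surgery_event"].map({True: 1.0, False: 0.0}).to_numpy(float)
        loc = P.df["location"].to_numpy(object)
        ok = cd.to_numpy() & ~np.isnan(t) & ~np.isnan(e) & \
            pd.Series(loc).isin(["L1", "L2", "L3"]).to_numpy()
        curves = km_estimate(t[ok], e[ok], loc[ok])
        pd.concat([c.to_frame() for c in curves.values()]).to_csv(
            out / "km_surgery_by_location.tsv", sep="\t", index=False)
        artifacts["km_surgery"] = out / "km_surgery_by_location.tsv"
        log["stages"]["km_logrank"] = logrank_test(t[ok], e[ok], loc[ok])
        if truth is not None:
            ev = truth.per_sample[["sample_id", "t_b1_to_b2", "t_b2_to_b3"]]
            behaviour_prevalence(P, ev).to_csv(
                out / "behaviour_prevalence.tsv", sep="\t", index=False)
            artifacts["behaviour_prevalence"] = out / "behaviour_prevalence.tsv"

        # --- power -----------------------------------------------------
        power_table([1.05, 1.1, 1.2, 1.5], [2000, 5000, 10000]).to_csv(
            out / "power.tsv", sep="\t", index=False)
        artifacts["power"] = out / "power.tsv"

        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        artifacts["run_log"] = out / "run_log.json"
    except Exception as exc:
        # remove partial outputs so a failed run leaves no half-bundle
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    return {k: str(v) for k, v in artifacts.items()}


def _continuum_labels(P: PhenotypeTable) -> np.ndarray:
    """Continuum groups: ileal/colonic/ileocolonic CD, UC, IBD-U."""
    df = P.df
    lab = np.full(len(df), None, dtype=object)
    cd = df["diagnosis"] == "CD"
    lab[(cd & (df["location"] == "L1")).to_numpy()] = "ilealCD"
    lab[(cd & (df["location"] == "L2")).to_numpy()] = "colonicCD"
    lab[(cd & (df["location"] == "L3")).to_numpy()] = "ileocolonicCD"
    lab[(df["diagnosis"] == "UC").to_numpy()] = "UC"
    lab[(df["diagnosis"] == "IBDU").to_numpy()] = "IBDU"
    return lab
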