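"""Per-variant subphenotype association scans.

Orchestrates the regression engines across all variants for one phenotype
target, with principal-component adjustment and optional conditioning on the
other phenotypes (disease location as dummies, behaviour as an ordinal code,
age at diagnosis as an inverse-normal score).  Provides BIC-based genetic
model selection for multicategory phenotypes, significance tiering at the
genome-wide (5e-8) and suggestive (1e-5) thresholds, and meta-analytic
combination of discovery with replication cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CovariateSet, GenotypeMatrix, PhenotypeTable, compute_pcs
from .models import (AssocResult, MetaResult, fit_binary_logistic, fit_linear,
                     fit_multinomial_logistic, fit_ordinal_logistic,
                     fit_weibull_aft, inverse_normal_transform, meta_fixed)

GENOME_WIDE = 5e-8
SUGGESTIVE = 1e-5

#: default phenotype -> model mapping (the selected models of the study)
PHENOTYPE_MODELS = {
    "location": "multinomial",   # L1/L2/L3, reference L2
    "behaviour": "ordinal",      # B1 < B2 < B3
    "extent": "binary",          # E3 vs E1+E2
    "age": "linear",             # inverse-normal age at diagnosis
    "surgery": "weibull",        # time to surgery/colectomy
    "upper_gi": "binary",
    "perianal": "binary",
}


@dataclass
class ScanConfig:
    phenotype: str
    model: str = "auto"
    n_pcs: int = 5
    condition_on: tuple = ()      # subset of {location, behaviour, age, extent}
    diagnosis: str | None = None  # restrict to CD or UC (default per phenotype)
    min_maf: float = 0.01
    max_missingness: float = 0.05
    genome_wide: float = GENOME_WIDE
    suggestive: float = SUGGESTIVE

    def __post_init__(self):
        if self.suggestive <= self.genome_wide:
            raise ValueError("suggestive threshold must exceed genome-wide")
        if self.model == "auto":
            if self.phenotype not in PHENOTYPE_MODELS:
                raise ValueError(f"unknown phenotype {self.phenotype!r}")
            self.model = PHENOTYPE_MODELS[self.phenotype]
        if self.diagnosis is None:
            self.diagnosis = {"location": "CD", "behaviour": "CD",
                              "extent": "UC", "upper_gi": "CD",
                              "perianal": "CD"}.get(self.phenotype)


def phenotype_response(P: PhenotypeTable, phenotype: str):
    """Extract the response vector(s) for a named phenotype target."""
    df = P.df
    if phenotype == "location":
        y = df["location"].where(df["location"].isin(["L1", "L2", "L3"]))
        return y.to_numpy(dtype=object)
    if phenotype == "behaviour":
        return df["behaviour"].to_numpy(dtype=object)
    if phenotype == "extent":
        e = df["extent"]
        return e.map({"E3": 1.0, "E2": 0.0, "E1": 0.0}).to_numpy(dtype=float)
    if phenotype == "age":
        return inverse_normal_transform(df["age_at_diagnosis"].to_numpy(float))
    if phenotype == "surgery":
        t = df["surgery_time_years"].to_numpy(dtype=float)
        e = df["surgery_event"].map({True: 1.0, False: 0.0}).to_numpy(float)
        return t, e
    if phenotype == "upper_gi":
        return df["upper_gi_L4"].map({True: 1.0, False: 0.0}).to_numpy(float)
    if phenotype == "perianal":
        return df["perianal"].map({True: 1.0, False: 0.0}).to_numpy(float)
    raise ValueError(f"unknown phenotype {phenotype!r}")


def conditioning_covariates(P: PhenotypeTable, condition_on) -> pd.DataFrame:
    """Encode conditioning phenotypes as numeric covariates.

    location -> two dummies (L1, L3; L2 reference), behaviour -> ordinal
    code 0/1/2, age -> inverse-normal score, extent -> E3 indicator.
    """
    df = P.df
    out = {}
    for c in condition_on:
        if c == "location":
            out["cond_L1"] = (df["location"] == "L1").astype(float).where(
                df["location"].notna())
            out["cond_L3"] = (df["location"] == "L3").astype(float).where(
                df["location"].notna())
        elif c == "behaviour":
            out["cond_behaviour"] = df["behaviour"].map(
                {"B1": 0.0, "B2": 1.0, "B3": 2.0})
        elif c == "age":
            out["cond_age"] = inverse_normal_transform(
                df["age_at_diagnosis"].to_numpy(float))
        elif c == "extent":
            out["cond_E3"] = (df["extent"] == "E3").astype(float).where(
                df["extent"].notna())
        else:
            raise ValueError(f"unknown conditioning phenotype {c!r}")
    return pd.DataFrame(out, index=df.index)


def _assemble_covariates(P, pcs: CovariateSet | None, cfg: ScanConfig):
    frames = []
    if pcs is not None:
        frames.append(pcs.data.iloc[:, :cfg.n_pcs].reset_index(drop=True))
    if cfg.condition_on:
        frames.append(conditioning_covariates(P, cfg.condition_on)
                      .reset_index(drop=True))
    if not frames:
        return None
    return CovariateSet(samples=P.sample_ids,
                        data=pd.concat(frames, axis=1))


def _fit_one(model, y, g, X, vid):
    if model == "linear":
        return fit_linear(y, g, X, variant_id=vid)
    if model == "binary":
        return fit_binary_logistic(y, g, X, variant_id=vid)
    if model == "ordinal":
        return fit_ordinal_logistic(y, g, X, variant_id=vid)
    if model == "multinomial":
        return fit_multinomial_logistic(y, g, X, variant_id=vid)
    if model == "weibull":
        t, e = y
        return fit_weibull_aft(t, e, g, X, variant_id=vid)
    raise ValueError(f"unknown model {model!r}")


def run_scan(G: GenotypeMatrix, P: PhenotypeTable, cfg: ScanConfig,
             pcs: CovariateSet | None = None) -> list[AssocResult]:
    """Fit the configured model at every variant passing the basic filters."""
    if cfg.diagnosis:
        keep = (P.df["diagnosis"] == cfg.diagnosis).to_numpy()
    else:
        keep = np.ones(len(P), dtype=bool)
    Psub = P.subset(keep)
    dos = G.dosages[keep]
    if pcs is None:
        sub_gm = GenotypeMatrix(samples=[G.samples[i] for i in np.where(keep)[0]],
                                variants=G.variants, dosages=dos)
        pcs = None if cfg.n_pcs == 0 else compute_pcs(sub_gm, k=cfg.n_pcs)
    else:
        pcs = CovariateSet(samples=Psub.sample_ids,
                           data=pcs.data.loc[keep].reset_index(drop=True))
    X = _assemble_covariates(Psub, pcs, cfg)
    y = phenotype_response(Psub, cfg.phenotype)

    mafs = np.array([GenotypeMatrix._maf(dos[:, j])
                     for j in range(dos.shape[1])])
    miss = np.isnan(dos).mean(axis=0)
    passing = (mafs >= cfg.min_maf) & (miss <= cfg.max_missingness)
    if not passing.any():
        raise ValueError("zero variants pass the MAF/missingness filters")
    results = []
    for j in np.where(passing)[0]:
        vid = G.variants[j].id
        try:
            res = _fit_one(cfg.model, y, dos[:, j], X, vid)
        except Exception as exc:  # keep scanning; record the failure
            res = AssocResult(variant_id=vid, model=cfg.model, effects={},
                              p=float("nan"), n_used=0, converged=False,
                              note=str(exc))
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# genetic model selection

def _composite_binary_bic(y, g, X, order) -> AssocResult:
    """Binary candidate on a multicategory response, scored on the full data.

    The top category is contrasted with the rest by logistic regression; the
    grouped categories are split by their genotype-free empirical frequencies
    so the composite likelihood is comparable with the ordinal and
    multinomial candidates fitted to the same observations.
    """
    yo = pd.Series(np.asarray(y, dtype=object))
    top = order[-1]
    yb = yo.map(lambda v: np.nan if pd.isna(v) else float(v == top))
    res = fit_binary_logistic(yb.to_numpy(dtype=float), g, X)
    rest = yo[yo.notna() & (yo != top)]
    counts = rest.value_counts()
    ll_rest = float((counts * np.log(counts / counts.sum())).sum())
    extra_df = max(len(counts) - 1, 0)
    return AssocResult(
        variant_id=res.variant_id, model="binary", effects=res.effects,
        p=res.p, n_used=res.n_used, converged=res.converged,
        loglik=res.loglik + ll_rest,
        df_model=res.df_model + extra_df)


def select_genetic_model(P: PhenotypeTable, G_panel: GenotypeMatrix,
                         phenotype: str, pcs: CovariateSet | None = None,
                         order: tuple | None = None,
                         diagnosis: str | None = None
                         ) -> tuple[str, dict]:
    """Pick binary/ordinal/multinomial for a multicategory phenotype by BIC.

    Each candidate is fitted at every panel variant; total BIC is summed over
    the panel and the minimum-total model returned.  Ties within 2 BIC units
    return the simplest model (binary < ordinal < multinomial) with a tie
    flag in the report.
    """
    if G_panel.n_variants < 10:
        raise ValueError("model selection needs a panel of >= 10 variants")
    cfgd = diagnosis or {"location": "CD", "behaviour": "CD",
                         "extent": "UC"}.get(phenotype)
    keep = ((P.df["diagnosis"] == cfgd).to_numpy() if cfgd
            else np.ones(len(P), bool))
    Psub = P.subset(keep)
    dos = G_panel.dosages[keep]
    if order is None:
        order = {"location": ("L2", "L3", "L1"),
                 "behaviour": ("B1", "B2", "B3"),
                 "extent": ("E1", "E2", "E3")}.get(phenotype)
    col = {"location": "location", "behaviour": "behaviour",
           "extent": "extent"}[phenotype]
    y = Psub.df[col].where(Psub.df[col].isin(order)).to_numpy(dtype=object)
    occupied = [c for c in order if (pd.Series(y) == c).any()]
    X = None
    if pcs is not None:
        X = CovariateSet(samples=Psub.sample_ids,
                         data=pcs.data.loc[keep].reset_index(drop=True))
    totals = {"binary": 0.0, "ordinal": 0.0, "multinomial": 0.0}
    for j in range(dos.shape[1]):
        g = dos[:, j]
        totals["binary"] += _composite_binary_bic(y, g, X, occupied).bic
        totals["ordinal"] += fit_ordinal_logistic(
            y, g, X, order=tuple(occupied)).bic
        if len(occupied) > 2:
            totals["multinomial"] += fit_multinomial_logistic(
                y, g, X, reference=occupied[0]).bic
        else:
            totals["multinomial"] = float("inf")
    simplicity = {"binary": 0, "ordinal": 1, "multinomial": 2}
    best = min(totals, key=lambda m: (totals[m], simplicity[m]))
    margin = sorted(totals.values())[1] - totals[best] if len(totals) > 1 else 0
    tie = margin < 2.0
    if tie:
        near = [m for m in totals if totals[m] - totals[best] < 2.0]
        best = min(near, key=lambda m: simplicity[m])
    return best, {"total_bic": totals, "margin": float(margin), "tie": tie}


# ---------------------------------------------------------------------------
# tiers and replication

def flag_significance(results: list[AssocResult],
                      cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Tier each result: genome_wide (p < 5e-8), suggestive (p < 1e-5), null."""
    gw = cfg.genome_wide if cfg else GENOME_WIDE
    sug = cfg.suggestive if cfg else SUGGESTIVE
    rows = []
    for r in results:
        if np.isnan(r.p):
            tier = "failed"
        elif r.p < gw:
            tier = "genome_wide"
        elif r.p < sug:
            tier = "suggestive"
        else:
            tier = "null"
        rows.append({"variant": r.variant_id, "model": r.model, "p": r.p,
                     "tier": tier, "n": r.n_used, "converged": r.converged})
    return pd.DataFrame(rows)


def combine_replication(discovery: list[AssocResult],
                        replication: list[AssocResult],
                        mode: str = "meta",
                        genome_wide: float = GENOME_WIDE,
                        suggestive: float = SUGGESTIVE,
                        replication_alpha: float = 0.05) -> pd.DataFrame:
    """Combine suggestive discovery signals with an independent cohort.

    ``mode='meta'`` pools by fixed-effect inverse variance and promotes a
    signal to genome-wide when the combined p falls below the threshold;
    ``mode='threshold'`` instead requires nominal same-direction replication.
    """
    rep_by_id = {r.variant_id: r for r in replication}
    rows = []
    for d in discovery:
        if np.isnan(d.p) or d.p >= suggestive:
            continue
        r = rep_by_id.get(d.variant_id)
        if r is None:
            warnings.warn(f"no replication result for {d.variant_id}; skipped")
            continue
        if mode == "meta":
            m = meta_fixed([d, r])
            promoted = m.p < genome_wide
            rows.append({"variant": d.variant_id, "beta": m.beta, "se": m.se,
                         "p_combined": m.p, "p_discovery": d.p,
                         "p_replication": r.p, "promoted": bool(promoted)})
        else:
            same_dir = np.sign(d.primary.beta) == np.sign(r.primary.beta)
            promoted = same_dir and r.p < replication_alpha and d.p < genome_wide
            rows.append({"variant": d.variant_id, "beta": d.primary.beta,
                         "se": d.primary.se, "p_combined": d.p,
                         "p_discovery": d.p, "p_replication": r.p,
                         "promoted": bool(promoted)})
    return pd.DataFrame(rows)


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Flatten AssocResults to the tabular output format."""
    rows = []
    for r in results:
        if not r.effects:
            rows.append({"variant": r.variant_id, "model": r.model,
                         "contrast": "", "beta": np.nan, "se": np.nan,
                         "or_hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": r.p, "n": r.n_used, "converged": r.converged})
            continue
        for name, eff in r.effects.items():
            lo, hi = eff.ci
            rows.append({"variant": r.variant_id, "model": r.model,
                         "contrast": name, "beta": eff.beta, "se": eff.se,
                         "or_hr": eff.or_hr, "ci_low": lo, "ci_high": hi,
                         "p": r.p, "n": r.n_used, "converged": r.converged})
    return pd.DataFrame(rows)
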