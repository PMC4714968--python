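"""Variance decomposition and analytic power.

The McKelvey-Zavoina pseudo-R-squared measures variance explained on the
latent logit scale: R2 = Var(eta_hat) / (Var(eta_hat) + pi^2/3), where
eta_hat is the fitted linear predictor of a binary (or ordinal, with the
same logistic latent variance) model.  ``variance_decomposition`` builds the
per-predictor and block R2 ledger for disease location (ileal vs colonic CD)
or extent (extensive vs non-extensive UC), applying the cohort filters used
for the adult-onset analysis (birth-year window, centres with excessive
smoking missingness removed).  ``analytic_power`` is the two-group normal
approximation for a per-allele association test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CovariateSet, GenotypeMatrix, PhenotypeTable
from .models import fit_binary_logistic
from .scan import GENOME_WIDE

LATENT_LOGISTIC_VAR = np.pi ** 2 / 3


@dataclass
class PowerSpec:
    maf: float
    odds_ratio: float
    alpha: float = GENOME_WIDE
    n1: int = 1000
    n2: int = 1000

    def __post_init__(self):
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def mckelvey_zavoina_r2(eta_hat: np.ndarray) -> float:
    """Latent-scale variance explained for a fitted logit linear predictor."""
    eta = np.asarray(eta_hat, dtype=float)
    if eta.size == 0 or np.isnan(eta).any():
        raise ValueError("fitted linear predictor required (no NaN)")
    v = float(eta.var())
    return v / (v + LATENT_LOGISTIC_VAR)


def _logit_r2(y, cols: pd.DataFrame) -> tuple[dict, float]:
    """Fit logit of y on the given columns; return coefs and MZ R2."""
    import statsmodels.api as sm

    Z = cols.to_numpy(float)
    ok = ~np.isnan(y) & ~np.isnan(Z).any(axis=1)
    exog = sm.add_constant(Z[ok], has_constant="add")
    fit = sm.Logit(y[ok], exog).fit(disp=0, maxiter=200)
    eta = exog[:, 1:] @ fit.params[1:]   # intercept does not contribute
    coefs = {c: (float(fit.params[i + 1]), float(fit.bse[i + 1]),
                 float(fit.pvalues[i + 1]))
             for i, c in enumerate(cols.columns)}
    return coefs, mckelvey_zavoina_r2(eta)


def variance_decomposition(P: PhenotypeTable, G: GenotypeMatrix,
                           outcome: str = "location",
                           score: np.ndarray | None = None,
                           birth_window: tuple[int, int] = (1955, 1985),
                           max_centre_smoking_missing: float = 0.60
                           ) -> pd.DataFrame:
    """Per-predictor and block McKelvey-Zavoina R2 table.

    Outcome ``location`` is ileal (L1) vs colonic (L2) Crohn's disease;
    ``extent`` is extensive (E3) vs non-extensive ulcerative colitis.
    Predictors: smoking (ever / current), age at diagnosis, year of birth,
    MHC variant dosage, the NOD2 risk-allele count (summed over NOD2-tagged
    variants), and the genetic risk score if supplied.  Single-predictor R2
    comes from one-predictor models, block rows from joint models.
    """
    df = P.df.copy()
    # filter: remove centres with excessive smoking missingness, then the
    # birth-year window for the adult-onset analysis
    sm_missing = df.groupby("site")["smoking"].apply(lambda s: s.isna().mean())
    bad_sites = set(sm_missing[sm_missing > max_centre_smoking_missing].index)
    keep = ~df["site"].isin(bad_sites)
    yob = df["year_of_birth"]
    keep &= yob.notna() & (yob >= birth_window[0]) & (yob <= birth_window[1])
    if outcome == "location":
        keep &= df["diagnosis"] == "CD"
        y_all = df["location"].map({"L1": 1.0, "L2": 0.0})
    elif outcome == "extent":
        keep &= df["diagnosis"] == "UC"
        y_all = df["extent"].map({"E3": 1.0, "E2": 0.0, "E1": 0.0})
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    keep = keep.to_numpy()
    if not keep.any():
        raise ValueError("no samples left after filters")
    sub = df.loc[keep]
    y = y_all.to_numpy(float)[keep]

    dosage = {v.id: G.dosages[keep, j] for j, v in enumerate(G.variants)}
    nod2_ids = [v.id for v in G.variants if v.locus_group.value == "NOD2"]
    mhc_ids = [v.id for v in G.variants if v.locus_group.value == "MHC"]
    preds = {
        "ever_smoker": sub["smoking"].map(
            {"smoker": 1.0, "ex": 1.0, "never": 0.0}).to_numpy(float),
        "current_smoker": sub["smoking"].map(
            {"smoker": 1.0, "ex": 0.0, "never": 0.0}).to_numpy(float),
        "age_at_diagnosis": sub["age_at_diagnosis"].to_numpy(float),
        "year_of_birth": sub["year_of_birth"].to_numpy(float),
    }
    for vid in mhc_ids:
        preds[f"{vid} (MHC)"] = dosage[vid]
    if nod2_ids:
        preds["NOD2 risk alleles"] = np.sum(
            [np.nan_to_num(dosage[v], nan=np.nanmean(dosage[v]))
             for v in nod2_ids], axis=0)
    if score is not None:
        preds["genetic_risk_score"] = np.asarray(score, float)[keep]

    # one common complete-case subset so single-predictor and block R2 are
    # computed on identical samples (required for nested comparisons)
    common = ~np.isnan(y)
    for x in preds.values():
        common &= ~np.isnan(np.asarray(x, float))
    if not common.any():
        raise ValueError("no samples left after filters")
    y = y[common]
    preds = {k: np.asarray(v, float)[common] for k, v in preds.items()}

    rows = []
    for name, x in preds.items():
        coefs, r2 = _logit_r2(y, pd.DataFrame({name: x}))
        beta, se, p = coefs[name]
        rows.append({"predictor": name, "beta": beta, "se": se, "p": p,
                     "r2_percent": 100 * r2})
    genetic = [k for k in preds if "MHC" in k or "NOD2" in k or "score" in k]
    smoking = ["ever_smoker", "current_smoker"]
    blocks = {
        "Genetic parameters": genetic,
        "Genetics and smoking": genetic + smoking,
        "All parameters": list(preds),
    }
    for bname, cols in blocks.items():
        if not cols:
            continue
        _, r2 = _logit_r2(y, pd.DataFrame({c: preds[c] for c in cols}))
        rows.append({"predictor": bname, "beta": np.nan, "se": np.nan,
                     "p": np.nan, "r2_percent": 100 * r2})
    return pd.DataFrame(rows)


def analytic_power(spec: PowerSpec) -> float:
    """Two-sided power of a per-allele (trend) test, normal approximation.

    SE^2 = (2 p (1-p))^-1 (1/n1 + 1/n2); power = Phi(|ln OR|/SE - z_{1-a/2})
    + Phi(-|ln OR|/SE - z_{1-a/2}).
    """
    p = spec.maf
    se = np.sqrt((1.0 / (2 * p * (1 - p))) * (1.0 / spec.n1 + 1.0 / spec.n2))
    z_crit = stats.norm.ppf(1 - spec.alpha / 2)
    ncp = abs(np.log(spec.odds_ratio)) / se
    return float(stats.norm.cdf(ncp - z_crit) + stats.norm.cdf(-ncp - z_crit))


def power_table(ors, sizes, maf: float = 0.30,
                alpha: float = GENOME_WIDE) -> pd.DataFrame:
    """Power over an OR x group-size grid (equal group sizes)."""
    rows = []
    for o in ors:
        for n in sizes:
            rows.append({"odds_ratio": o, "n_per_group": n, "maf": maf,
                         "alpha": alpha,
                         "power": analytic_power(PowerSpec(
                             maf=maf, odds_ratio=o, alpha=alpha, n1=n, n2=n))})
    return pd.DataFrame(rows)
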