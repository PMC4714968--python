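"""Genetic risk scores and their downstream analyses.

A risk score is a per-sample weighted sum of risk-allele dosages, with
per-locus weights on the natural-log odds-ratio scale.  The CD-vs-UC score
weights each locus by the difference of its CD and UC log odds ratios (or,
in the case-only default, by the case-case CD-vs-UC log OR directly) and is
the score used for continuum placement, cross-validated classification, and
outlier-based misclassification detection.  SNP and HLA-allele dosages are
treated identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import CovariateSet, GenotypeMatrix, PhenotypeTable
from .models import fit_binary_logistic, fit_linear

#: the published score-association multiplicity correction: 15 phenotype-score
#: combinations, so significance requires p < 0.05 / 15
SCORE_COMBINATIONS = 15

#: raw-score outlier thresholds for candidate misdiagnoses (natural-log units)
OUTLIER_LO, OUTLIER_HI = -2.0, 2.0
#: extreme-tail thresholds for the clinical-characteristics comparison
EXTREME_LO, EXTREME_HI = -2.0, 3.0


@dataclass
class EffectPanel:
    """Per-locus score weights: CD and UC log ORs vs a common reference."""

    table: pd.DataFrame  # columns: id, w_CD, w_UC, is_hla, locus_group

    def __post_init__(self):
        t = self.table
        if t["id"].duplicated().any():
            raise ValueError("duplicate locus ids in effect panel")
        if not np.isfinite(t[["w_CD", "w_UC"]].to_numpy()).all():
            raise ValueError("non-finite weights in effect panel")

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EffectPanel":
        return cls(pd.read_csv(path, sep="\t", dtype={"id": str}))


@dataclass
class ScoreSet:
    """Per-sample raw and standardized scores for one contrast."""

    samples: list[str]
    raw: np.ndarray           # natural-log odds units
    contrast: str

    @property
    def standardized(self) -> np.ndarray:
        sd = self.raw.std()
        if sd == 0:
            return np.zeros_like(self.raw)
        return (self.raw - self.raw.mean()) / sd


def estimate_effect_panel(G: GenotypeMatrix, labels, X: CovariateSet | None = None,
                          mode: str = "univariate") -> EffectPanel:
    """Per-locus log-OR weights from labelled training data.

    ``labels`` holds ``CD``/``UC``/``control`` (three-class mode: w_CD and
    w_UC are separate case-control log ORs) or just ``CD``/``UC`` (case-only
    mode: the case-case CD-vs-UC log OR is stored as w_CD with w_UC = 0, so
    the CD-vs-UC difference weight equals it).  Case-only ileal-vs-colonic
    panels work the same way with labels ``L1``/``L2``.  ``mode='joint'``
    fits all loci together in one multivariable logistic model.
    Monomorphic loci get weight 0 with a warning note in the table.
    """
    lab = pd.Series(np.asarray(labels, dtype=object))
    classes = sorted(set(lab.dropna()))
    if len(classes) < 2:
        raise ValueError("need >= 2 label classes")
    has_control = "control" in classes
    cases = [c for c in classes if c != "control"]

    def _per_locus(y01, mask):
        rows = []
        dos = G.dosages[mask]
        if mode == "joint":
            betas = _joint_logistic(y01[mask], dos, X, mask)
            for j, v in enumerate(G.variants):
                rows.append((v.id, betas[j]))
            return dict(rows)
        for j, v in enumerate(G.variants):
            col = dos[:, j]
            ok = ~np.isnan(col)
            if np.nanstd(col) == 0 or not ok.any():
                rows.append((v.id, 0.0))
                continue
            Xm = X.data.loc[mask].reset_index(drop=True) if X is not None else None
            res = fit_binary_logistic(y01[mask], col, Xm)
            rows.append((v.id, res.primary.beta if res.converged else 0.0))
        return dict(rows)

    if has_control:
        w_cd = _per_locus((lab == cases[0]).astype(float).where(
            lab.isin([cases[0], "control"])).to_numpy(float),
            lab.isin([cases[0], "control"]).to_numpy())
        w_uc = _per_locus((lab == cases[1]).astype(float).where(
            lab.isin([cases[1], "control"])).to_numpy(float),
            lab.isin([cases[1], "control"]).to_numpy())
        # conventional orientation: w_CD from the CD arm, w_UC from the UC arm
        if cases[0] != "CD" and "CD" in cases:
            w_cd, w_uc = w_uc, w_cd
        wcd = {k: w_cd[k] for k in w_cd}
        wuc = {k: w_uc[k] for k in w_uc}
    else:
        a, b = ("CD", "UC") if set(cases) == {"CD", "UC"} else (cases[0], cases[1])
        y = (lab == a).astype(float).where(lab.notna()).to_numpy(float)
        w = _per_locus(y, lab.notna().to_numpy())
        wcd = w
        wuc = {k: 0.0 for k in w}
    table = pd.DataFrame({
        "id": G.variant_ids,
        "w_CD": [wcd[i] for i in G.variant_ids],
        "w_UC": [wuc[i] for i in G.variant_ids],
        "is_hla": [v.is_hla for v in G.variants],
        "locus_group": [v.locus_group.value for v in G.variants],
    })
    return EffectPanel(table=table)


def _joint_logistic(y, dos, X, mask):
    import statsmodels.api as sm

    d = dos.copy()
    means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(means, idx[1])
    cols = [d]
    if X is not None:
        cols.append(X.data.loc[mask].to_numpy(float))
    exog = sm.add_constant(np.column_stack(cols))
    ok = ~np.isnan(y)
    fit = sm.Logit(y[ok], exog[ok]).fit(disp=0, maxiter=200)
    return np.asarray(fit.params[1:1 + dos.shape[1]])


def build_score_weights(panel: EffectPanel, contrast: str = "CD_vs_UC"
                        ) -> pd.Series:
    """Weight vector for a contrast: CD_vs_UC = w_CD - w_UC; CD; UC."""
    t = panel.table.set_index("id")
    if contrast == "CD_vs_UC":
        w = t["w_CD"] - t["w_UC"]
    elif contrast == "CD":
        w = t["w_CD"]
    elif contrast == "UC":
        w = t["w_UC"]
    elif contrast == "ileal_vs_colonic":
        w = t["w_CD"] - t["w_UC"]   # case-only panel trained on L1 vs L2
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return w


def exclude_loci(panel: EffectPanel, tags: set) -> EffectPanel:
    """Drop loci whose locus_group is in ``tags`` (e.g. {NOD2, MHC, MST1})."""
    known = {"NOD2", "MHC", "MST1", "OTHER"}
    bad = set(tags) - known
    if bad:
        raise ValueError(f"unknown locus group(s): {sorted(bad)}")
    keep = ~panel.table["locus_group"].isin(tags)
    return EffectPanel(table=panel.table[keep].reset_index(drop=True))


def score_samples(G: GenotypeMatrix, weights: pd.Series,
                  contrast: str = "CD_vs_UC", center: bool = False
                  ) -> ScoreSet:
    """S_i = sum_j w_j * dosage_ij with per-variant mean imputation.

    ``center=True`` subtracts the cohort mean so the raw natural-log score
    is anchored at 0 (the scale on which the +-2 outlier thresholds live).
    """
    have = [i for i in weights.index if i in set(G.variant_ids)]
    if len(have) < 0.5 * len(weights):
        raise ValueError(
            f"only {len(have)}/{len(weights)} weighted loci present in matrix")
    sub = G.subset_variants(have)
    d = sub.imputed()
    raw = d @ weights.loc[have].to_numpy(float)
    if center:
        raw = raw - raw.mean()
    return ScoreSet(samples=list(G.samples), raw=raw, contrast=contrast)


def associate_score(scores: ScoreSet, phenotype, X: CovariateSet | None = None,
                    kind: str = "linear") -> dict:
    """Regress a phenotype on the standardized score with covariates.

    Returns the standardized effect, SE, p, and a significance flag at the
    Bonferroni threshold 0.05 / 15 for the phenotype-score combinations.
    """
    s = scores.standardized
    if kind == "linear":
        y = np.asarray(phenotype, dtype=float)
        ok = ~np.isnan(y)
        y = (y - np.nanmean(y)) / np.nanstd(y)
        res = fit_linear(y, s, X)
    elif kind == "binary":
        res = fit_binary_logistic(np.asarray(phenotype, dtype=float), s, X)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    thr = 0.05 / SCORE_COMBINATIONS
    return {"beta": res.primary.beta, "se": res.primary.se, "p": res.p,
            "n": res.n_used, "significant": bool(res.p < thr),
            "threshold": thr}


def crossval_auc(G: GenotypeMatrix, P: PhenotypeTable,
                 train_mask, test_mask, class_a: str, class_b: str,
                 label_column: str = "location",
                 train_labels: str = "diagnosis",
                 contrast: str = "CD_vs_UC",
                 pcs: CovariateSet | None = None,
                 n_boot: int = 2000, seed: int = 0) -> dict:
    """Held-out AUC of a score for distinguishing two classes.

    Weights are estimated only on ``train_mask`` samples (e.g. non-UK sites)
    from ``train_labels``; the AUC is the rank statistic on ``test_mask``
    samples for ``class_a`` vs ``class_b`` of ``label_column``, with a
    stratified bootstrap percentile CI.
    """
    train_mask = np.asarray(train_mask, bool)
    test_mask = np.asarray(test_mask, bool)
    sub_train = GenotypeMatrix(
        samples=[s for s, m in zip(G.samples, train_mask) if m],
        variants=G.variants, dosages=G.dosages[train_mask])
    Xt = None
    if pcs is not None:
        Xt = CovariateSet(samples=sub_train.samples,
                          data=pcs.data.loc[train_mask].reset_index(drop=True))
    panel = estimate_effect_panel(
        sub_train, P.df.loc[train_mask, train_labels].to_numpy(object), Xt)
    w = build_score_weights(panel, contrast)
    scores = score_samples(G, w, contrast)
    lab = P.df[label_column].to_numpy(object)
    sel = test_mask & pd.Series(lab).isin([class_a, class_b]).to_numpy()
    y = (lab[sel] == class_a).astype(int)
    s = scores.raw[sel]
    if len(set(y)) < 2:
        raise ValueError("held-out set does not contain both classes")
    auc = roc_auc_score(y, s)
    rng = np.random.default_rng(seed)
    idx1, idx0 = np.where(y == 1)[0], np.where(y == 0)[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        i1 = rng.choice(idx1, idx1.size)
        i0 = rng.choice(idx0, idx0.size)
        ii = np.concatenate([i1, i0])
        boots[b] = roc_auc_score(y[ii], s[ii])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"auc": float(auc), "ci": (float(lo), float(hi)),
            "n_test": int(sel.sum()), "n_train": int(train_mask.sum())}


def flag_outliers(scores: ScoreSet, P: PhenotypeTable,
                  lo: float = OUTLIER_LO, hi: float = OUTLIER_HI,
                  seed: int = 0) -> pd.DataFrame:
    """Flag candidate misdiagnoses from raw CD-vs-UC scores.

    CD cases with score <= ``lo`` and UC cases with score >= ``hi`` are
    outliers (the wrong tail for their diagnosis).  A site-matched random
    non-outlier comparator is drawn per outlier where available; the
    returned table has columns sample_id, diagnosis, score, arm
    ('outlier'/'non_outlier') and site.
    """
    df = P.df
    s = pd.Series(scores.raw, index=df.index)
    diag = df["diagnosis"]
    is_out = ((diag == "CD") & (s <= lo)) | ((diag == "UC") & (s >= hi))
    out_rows = df.loc[is_out, ["sample_id", "diagnosis", "site"]].copy()
    out_rows["score"] = s[is_out]
    out_rows["arm"] = "outlier"
    rng = np.random.default_rng(seed)
    comp_idx: list[int] = []
    pool = df.index[~is_out & diag.isin(["CD", "UC"])]
    by_site = {k: list(v) for k, v in df.loc[pool].groupby("site").groups.items()}
    taken: set[int] = set()
    for _, row in df.loc[is_out].iterrows():
        cand = [i for i in by_site.get(row["site"], []) if i not in taken]
        if not cand:
            cand = [i for i in pool if i not in taken]
        if not cand:
            continue
        pick = int(rng.choice(cand))
        taken.add(pick)
        comp_idx.append(pick)
    comp = df.loc[comp_idx, ["sample_id", "diagnosis", "site"]].copy()
    comp["score"] = s[comp_idx]
    comp["arm"] = "non_outlier"
    return pd.concat([out_rows, comp], ignore_index=True)


def enrichment_test(outlier_table: pd.DataFrame, P: PhenotypeTable) -> dict:
    """Test whether outliers are enriched for revised diagnoses.

    Logistic regression of the revision flag on outlier status with a
    disease-location covariate; Fisher's exact test is the fallback when any
    2x2 cell count falls below 5.  Degenerate (all-same) flags return p=1.
    """
    df = P.df.set_index("sample_id")
    t = outlier_table.copy()
    t["revised"] = df.loc[t["sample_id"], "diagnosis_revised"].map(
        {True: 1.0, False: 0.0}).to_numpy()
    t = t.dropna(subset=["revised"])
    if t.empty or (t["arm"] == "outlier").sum() == 0 or \
            (t["arm"] == "non_outlier").sum() == 0:
        raise ValueError("both arms must be non-empty")
    a = t[t["arm"] == "outlier"]
    b = t[t["arm"] == "non_outlier"]
    table = np.array([[(a["revised"] == 1).sum(), (a["revised"] == 0).sum()],
                      [(b["revised"] == 1).sum(), (b["revised"] == 0).sum()]])
    rate_out = float(table[0, 0] / table[0].sum())
    rate_non = float(table[1, 0] / table[1].sum())
    if t["revised"].nunique() < 2:
        return {"p": 1.0, "rate_outlier": rate_out, "rate_non_outlier": rate_non,
                "method": "degenerate", "n_outlier": int(table[0].sum()),
                "n_non_outlier": int(table[1].sum())}
    if (table < 5).any():
        p = float(stats.fisher_exact(table)[1])
        method = "fisher"
        beta = float("nan")
    else:
        loc = df.loc[t["sample_id"], "location"].to_numpy(object)
        X = CovariateSet(samples=list(t["sample_id"]), data=pd.DataFrame({
            "loc_L1": [1.0 if l == "L1" else 0.0 for l in loc],
            "loc_L3": [1.0 if l == "L3" else 0.0 for l in loc]}))
        res = fit_binary_logistic(
            t["revised"].to_numpy(float),
            (t["arm"] == "outlier").to_numpy(float), X)
        if res.converged:
            p, beta, method = res.p, res.primary.beta, "logistic"
        else:
            p, beta, method = float(stats.fisher_exact(table)[1]), float("nan"), "fisher"
    return {"p": p, "beta": beta, "rate_outlier": rate_out,
            "rate_non_outlier": rate_non, "method": method,
            "n_outlier": int(table[0].sum()),
            "n_non_outlier": int(table[1].sum())}


def compare_groupings(G: GenotypeMatrix, labels3) -> dict:
    """BIC evidence for 3 genetic groups (ileal CD, colonic CD, UC) vs 2.

    Per locus, Gaussian models of dosage with either two group means (CD
    grouped) or three are compared; DeltaBIC = BIC(2 groups) - BIC(3 groups)
    summed over loci, so positive totals favour the three-group model.
    """
    lab = pd.Series(np.asarray(labels3, dtype=object))
    need = {"ilealCD", "colonicCD", "UC"}
    missing = need - set(lab.dropna())
    if missing:
        raise ValueError(f"missing label class(es): {sorted(missing)}")
    ok = lab.isin(need).to_numpy()
    lab2 = lab.map({"ilealCD": "CD", "colonicCD": "CD", "UC": "UC"})
    per_locus = {}
    total = 0.0
    for j, v in enumerate(G.variants):
        d = G.dosages[ok, j]
        good = ~np.isnan(d)
        d = d[good]
        g3 = lab[ok].to_numpy(object)[good]
        g2 = lab2[ok].to_numpy(object)[good]
        bic3 = _group_mean_bic(d, g3, 3)
        bic2 = _group_mean_bic(d, g2, 2)
        delta = bic2 - bic3
        per_locus[v.id] = float(delta)
        total += delta
    return {"delta_bic": float(total), "per_locus": per_locus,
            "favours": "3_groups" if total > 0 else "2_groups"}


def _group_mean_bic(d: np.ndarray, groups: np.ndarray, k_means: int) -> float:
    n = d.size
    resid = 0.0
    for gname in pd.unique(groups):
        sub = d[groups == gname]
        resid += ((sub - sub.mean()) ** 2).sum()
    sigma2 = max(resid / n, 1e-12)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    df = k_means + 1   # group means + common variance
    return float(-2 * ll + df * np.log(n))


def continuum_summary(scores: ScoreSet, labels) -> pd.DataFrame:
    """Group means with 95% CIs of the CD-vs-UC score, ordered by mean.

    Accepts any grouping including intermediate phenotypes (L3, IBD-U);
    the output is the data behind a continuum/violin figure.
    """
    lab = pd.Series(np.asarray(labels, dtype=object))
    rows = []
    for gname in sorted(set(lab.dropna())):
        s = scores.raw[(lab == gname).to_numpy()]
        if s.size == 0:
            continue
        m = float(s.mean())
        sem = float(s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else 0.0
        rows.append({"group": gname, "n": int(s.size), "mean": m,
                     "sem": sem, "ci_low": m - 1.96 * sem,
                     "ci_high": m + 1.96 * sem})
    return pd.DataFrame(rows).sort_values("mean").reset_index(drop=True)


def score_histogram(scores: ScoreSet, labels, bin_width: float = 0.1
                    ) -> pd.DataFrame:
    """Binned score histogram per group (the misdiagnosis-figure data)."""
    lab = pd.Series(np.asarray(labels, dtype=object))
    lo = np.floor(scores.raw.min() / bin_width) * bin_width
    hi = np.ceil(scores.raw.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    rows = []
    for gname in sorted(set(lab.dropna())):
        counts, _ = np.histogram(scores.raw[(lab == gname).to_numpy()], edges)
        for e, c in zip(edges[:-1], counts):
            rows.append({"group": gname, "bin_left": float(e),
                         "count": int(c)})
    return pd.DataFrame(rows)
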