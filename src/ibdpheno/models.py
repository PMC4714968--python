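"""Association regression engines.

One maximum-likelihood engine per response kind — linear, binary logistic,
proportional-odds ordinal, baseline-category multinomial, and right-censored
Weibull accelerated-failure-time — all sharing the contract
``fit_*(y, g, X) -> AssocResult`` where ``g`` is a per-allele dosage (0-2)
and ``X`` an optional covariate frame (principal components, conditioning
phenotypes).  Complete-case analysis per fit.  The ordinal engine is
parameterised so that an odds ratio above one means more complicated
disease; the Weibull engine reports both the AFT coefficient and the derived
log hazard ratio (-beta * shape) with a delta-method standard error.

Also provides the rank-based inverse-normal transform used for age at
diagnosis and inverse-variance fixed-effect meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.numdiff import approx_hess
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ContrastEffect", "AssocResult", "MetaResult",
    "inverse_normal_transform", "fit_linear", "fit_binary_logistic",
    "fit_ordinal_logistic", "fit_multinomial_logistic", "fit_weibull_aft",
    "meta_fixed",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class ContrastEffect:
    beta: float
    se: float

    @property
    def or_hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (float(np.exp(self.beta - _Z975 * self.se)),
                float(np.exp(self.beta + _Z975 * self.se)))

    @property
    def wald_p(self) -> float:
        if self.se <= 0:
            return float("nan")
        return float(2 * stats.norm.sf(abs(self.beta) / self.se))


@dataclass
class AssocResult:
    """Fitted per-variant effects for one phenotype model."""

    variant_id: str
    model: str
    effects: dict[str, ContrastEffect]
    p: float
    n_used: int
    converged: bool
    intercepts: dict[str, float] = field(default_factory=dict)
    shape: float | None = None  # Weibull shape k
    loglik: float | None = None
    df_model: int | None = None
    note: str = ""

    @property
    def primary(self) -> ContrastEffect:
        """First (headline) contrast."""
        return next(iter(self.effects.values()))

    @property
    def bic(self) -> float:
        if self.loglik is None or self.df_model is None:
            return float("nan")
        return float(-2 * self.loglik + self.df_model * np.log(self.n_used))


@dataclass
class MetaResult:
    variant_id: str
    beta: float
    se: float
    z: float
    p: float
    inputs: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# helpers

def _complete_cases(*arrays):
    """Boolean mask of rows with no missing value across the inputs."""
    n = len(arrays[0])
    ok = np.ones(n, dtype=bool)
    for a in arrays:
        if a is None:
            continue
        arr = np.asarray(a, dtype=object)
        if arr.ndim == 1:
            ok &= ~pd.isna(arr)
        else:
            ok &= ~pd.isna(arr).any(axis=1)
    return ok


def _design(g, X, mask):
    cols = {"g": np.asarray(g, dtype=float)[mask]}
    names = ["g"]
    if X is not None:
        Xdf = X.data if hasattr(X, "data") else pd.DataFrame(X)
        for c in Xdf.columns:
            cols[c] = Xdf[c].to_numpy(dtype=float)[mask]
            names.append(c)
    return pd.DataFrame(cols), names


def _covariate_matrix(X, mask):
    if X is None:
        return None
    Xdf = X.data if hasattr(X, "data") else pd.DataFrame(X)
    return Xdf.to_numpy(dtype=float)[mask]


# ---------------------------------------------------------------------------
# transforms and meta-analysis

def inverse_normal_transform(y, ties: str = "average") -> np.ndarray:
    """Rank-based inverse-normal transform Phi^-1((rank - 0.5) / n).

    Ties receive the average rank, so the output is invariant to any
    monotone rescaling of the input.  Missing values propagate as NaN.
    """
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    vals = y[ok]
    if np.unique(vals).size < 2:
        raise ValueError("inverse-normal transform needs >= 2 distinct values")
    ranks = stats.rankdata(vals, method=ties)
    out = np.full(y.shape, np.nan)
    out[ok] = stats.norm.ppf((ranks - 0.5) / vals.size)
    return out


def zscore_transform(y) -> np.ndarray:
    """Plain (y - mean) / sd alternative to the rank-based transform."""
    y = np.asarray(y, dtype=float)
    mu, sd = np.nanmean(y), np.nanstd(y)
    if sd == 0:
        raise ValueError("constant vector")
    return (y - mu) / sd


def meta_fixed(results: list[AssocResult], contrast: str | None = None) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study effects."""
    if len(results) < 2:
        raise ValueError("meta-analysis needs >= 2 studies")
    vid = results[0].variant_id
    if any(r.variant_id != vid for r in results):
        raise ValueError("mismatched variant ids in meta-analysis")
    pairs = []
    for r in results:
        eff = r.effects[contrast] if contrast else r.primary
        pairs.append((eff.beta, eff.se))
    w = np.array([1.0 / se**2 for _, se in pairs])
    b = np.array([beta for beta, _ in pairs])
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    return MetaResult(variant_id=vid, beta=beta, se=se, z=float(z),
                      p=float(2 * stats.norm.sf(abs(z))), inputs=pairs)


# ---------------------------------------------------------------------------
# linear

def fit_linear(y, g, X=None, variant_id: str = "") -> AssocResult:
    mask = _complete_cases(y, g, X.data if hasattr(X, "data") else X)
    yv = np.asarray(y, dtype=float)[mask]
    design, names = _design(g, X, mask)
    exog = sm.add_constant(design.to_numpy(), has_constant="add")
    if yv.size < exog.shape[1] + 1:
        raise ValueError("too few complete cases")
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise ValueError(f"collinear design among columns {['const'] + names}")
    fit = sm.OLS(yv, exog).fit()
    eff = ContrastEffect(beta=float(fit.params[1]), se=float(fit.bse[1]))
    return AssocResult(
        variant_id=variant_id, model="linear",
        effects={"per_allele": eff}, p=float(fit.pvalues[1]),
        n_used=int(yv.size), converged=True,
        intercepts={"const": float(fit.params[0])},
        loglik=float(fit.llf), df_model=int(exog.shape[1]) + 1)


# ---------------------------------------------------------------------------
# binary logistic

def fit_binary_logistic(y, g, X=None, variant_id: str = "",
                        p_method: str = "wald") -> AssocResult:
    mask = _complete_cases(y, g, X.data if hasattr(X, "data") else X)
    yv = np.asarray(y, dtype=float)[mask]
    classes = np.unique(yv)
    if classes.size != 2:
        raise ValueError("binary logistic needs exactly two classes present")
    yb = (yv == classes.max()).astype(float)
    design, names = _design(g, X, mask)
    exog = sm.add_constant(design.to_numpy(), has_constant="add")
    converged, note = True, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yb, exog).fit(disp=0, maxiter=100, tol=1e-10)
            converged = bool(fit.mle_retvals.get("converged", True))
            if abs(fit.params[1]) > 15 or not np.isfinite(fit.bse).all():
                converged, note = False, "possible perfect separation"
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            return AssocResult(
                variant_id=variant_id, model="binary",
                effects={"per_allele": ContrastEffect(beta=float("nan"),
                                                      se=float("nan"))},
                p=float("nan"), n_used=int(yb.size), converged=False,
                loglik=None, df_model=None, note=f"separation: {exc}")
    beta = float(fit.params[1])
    se = float(fit.bse[1]) if converged else float("nan")
    if p_method == "lrt" and converged:
        null_exog = np.delete(exog, 1, axis=1)
        fit0 = sm.Logit(yb, null_exog).fit(disp=0, maxiter=100)
        lr = 2 * (fit.llf - fit0.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    else:
        p = float(2 * stats.norm.sf(abs(beta) / se)) if converged else float("nan")
    return AssocResult(
        variant_id=variant_id, model="binary",
        effects={"per_allele": ContrastEffect(beta=beta, se=se)},
        p=p, n_used=int(yb.size), converged=converged,
        intercepts={"const": float(fit.params[0])},
        loglik=float(fit.llf), df_model=int(exog.shape[1]), note=note)


# ---------------------------------------------------------------------------
# proportional-odds ordinal logistic

def fit_ordinal_logistic(y, g, X=None, variant_id: str = "",
                         order: tuple = ("B1", "B2", "B3")) -> AssocResult:
    """Proportional-odds model logit P(Y > k) = beta*g + gamma'X - theta_k.

    ``order`` gives the category ordering from least to most severe; with
    only two occupied categories the fit collapses to binary logistic.
    p-value by likelihood-ratio test of beta = 0.
    """
    yo = pd.Series(np.asarray(y, dtype=object))
    mask = _complete_cases(yo, g, X.data if hasattr(X, "data") else X)
    yv = yo[mask]
    present = [c for c in order if (yv == c).any()]
    if len(present) < 2:
        raise ValueError("ordinal fit needs >= 2 occupied categories")
    codes = pd.Categorical(yv, categories=present, ordered=True)
    design, names = _design(g, X, mask)
    mod = OrderedModel(codes.codes.astype(float), design.to_numpy(),
                       distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = mod.fit(method="lbfgs", disp=0, maxiter=1000, pgtol=1e-12)
        # polish: a few BFGS steps from the L-BFGS optimum tighten the
        # solution to the tolerances the collapse identities require
        fit = mod.fit(start_params=fit.params, method="bfgs", disp=0,
                      maxiter=100, gtol=1e-11)
        if len(names) > 1:
            null = OrderedModel(codes.codes.astype(float),
                                design.drop(columns="g").to_numpy(),
                                distr="logit").fit(method="lbfgs", disp=0,
                                                   maxiter=1000, pgtol=1e-12)
            null_llf = float(null.llf)
        else:
            # intercept-only ordinal model: category frequencies in closed form
            counts = np.bincount(codes.codes, minlength=len(present))
            null_llf = float((counts * np.log(counts / counts.sum())).sum())
    k = design.shape[1]
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    thetas = mod.transform_threshold_params(fit.params)[1:-1]
    lr = 2 * (fit.llf - null_llf)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    monotone = bool(np.all(np.diff(thetas) > 0)) if len(thetas) > 1 else True
    return AssocResult(
        variant_id=variant_id, model="ordinal",
        effects={"proportional_odds": ContrastEffect(beta=beta, se=se)},
        p=p, n_used=int(mask.sum()),
        converged=bool(fit.mle_retvals.get("converged", True)) and monotone,
        intercepts={f"theta_{i + 1}": float(t) for i, t in enumerate(thetas)},
        loglik=float(fit.llf), df_model=int(k + len(thetas)),
        note="" if monotone else "non-monotone cutpoints")


# ---------------------------------------------------------------------------
# baseline-category multinomial logistic

def fit_multinomial_logistic(y, g, X=None, variant_id: str = "",
                             reference: str = "L2") -> AssocResult:
    """Baseline-category multinomial with per-contrast Wald SEs.

    The overall p-value is a likelihood-ratio test on the genotype term
    ((K - 1) degrees of freedom).  Contrasts are named ``<cat>_vs_<ref>``.
    """
    yo = pd.Series(np.asarray(y, dtype=object))
    mask = _complete_cases(yo, g, X.data if hasattr(X, "data") else X)
    yv = yo[mask]
    cats = sorted(set(yv))
    if reference not in cats:
        raise ValueError(f"reference category {reference!r} not occupied; "
                         f"drop it or pick one of {cats}")
    cats = [reference] + [c for c in cats if c != reference]
    if len(cats) < 2:
        raise ValueError("multinomial fit needs >= 2 occupied categories; "
                         "drop empty categories first")
    codes = pd.Categorical(yv, categories=cats).codes.astype(int)
    design, names = _design(g, X, mask)
    exog = sm.add_constant(design.to_numpy(), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(codes, exog).fit(disp=0, maxiter=200, tol=1e-10,
                                          method="newton")
        null = sm.MNLogit(codes, np.delete(exog, 1, axis=1)).fit(
            disp=0, maxiter=200, tol=1e-10, method="newton")
    effects, intercepts = {}, {}
    bse = np.asarray(fit.bse)
    params = np.asarray(fit.params)
    for j, cat in enumerate(cats[1:]):
        effects[f"{cat}_vs_{reference}"] = ContrastEffect(
            beta=float(params[1, j]), se=float(bse[1, j]))
        intercepts[f"alpha_{cat}"] = float(params[0, j])
    lr = 2 * (fit.llf - null.llf)
    df = len(cats) - 1
    p = float(stats.chi2.sf(max(lr, 0.0), df=df))
    finite = bool(np.isfinite(params).all() and np.isfinite(bse).all())
    return AssocResult(
        variant_id=variant_id, model="multinomial", effects=effects,
        p=p if finite else float("nan"), n_used=int(mask.sum()),
        converged=bool(fit.mle_retvals.get("converged", True)) and finite,
        intercepts=intercepts, loglik=float(fit.llf),
        df_model=int(exog.shape[1] * df))


# ---------------------------------------------------------------------------
# Weibull accelerated failure time

def _weibull_negll(params, logt, event, Z):
    # params: [mu, coefs..., log_sigma]
    mu = params[0]
    log_sigma = params[-1]
    coefs = params[1:-1]
    sigma = np.exp(log_sigma)
    eta = mu + (Z @ coefs if Z.size else 0.0)
    z = (logt - eta) / sigma
    ez = np.exp(np.clip(z, -700, 700))
    ll = np.where(event == 1, -log_sigma - logt + z - ez, -ez)
    return -ll.sum()


def fit_weibull_aft(time, event, g=None, X=None, variant_id: str = "",
                    fix_shape: float | None = None) -> AssocResult:
    """Right-censored Weibull AFT: log T = mu + beta*g + gamma'X + sigma*W.

    W has a standard Gumbel (minimum) distribution; shape k = 1/sigma.  The
    proportional-hazards effect is log HR = -beta * k, reported with a
    delta-method SE from the joint (beta, log sigma) covariance.  With
    ``fix_shape`` the shape is held fixed (shape 1 = exponential).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    mask = _complete_cases(t, e, g, X.data if hasattr(X, "data") else X)
    t, e = t[mask], e[mask]
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if e.sum() < 1:
        raise ValueError("no events observed")
    if g is not None:
        design, names = _design(g, X, mask)
    elif X is not None:
        Xdf = X.data if hasattr(X, "data") else pd.DataFrame(X)
        design = Xdf.loc[mask].reset_index(drop=True)
        names = list(design.columns)
    else:
        design, names = pd.DataFrame(index=range(mask.sum())), []
    Z = design.to_numpy(dtype=float) if names else np.empty((t.size, 0))
    logt = np.log(t)

    fixed = fix_shape is not None
    x0 = np.concatenate([[logt.mean()], np.zeros(Z.shape[1]),
                         [0.0 if not fixed else -np.log(fix_shape)]])

    if fixed:
        log_sigma0 = -np.log(fix_shape)

        def nll(p):
            return _weibull_negll(np.concatenate([p, [log_sigma0]]),
                                  logt, e, Z)
        res = optimize.minimize(nll, x0[:-1], method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        full = np.concatenate([res.x, [log_sigma0]])
        hess = approx_hess(res.x, nll)
        cov = np.linalg.pinv(hess)
        cov_full = np.zeros((full.size, full.size))
        cov_full[:-1, :-1] = cov
    else:
        res = optimize.minimize(_weibull_negll, x0, args=(logt, e, Z),
                                method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        full = res.x
        hess = approx_hess(full, _weibull_negll, args=(logt, e, Z))
        cov_full = np.linalg.pinv(hess)

    sigma = float(np.exp(full[-1]))
    k = 1.0 / sigma
    effects: dict[str, ContrastEffect] = {}
    if names:
        beta = float(full[1])
        se_beta = float(np.sqrt(max(cov_full[1, 1], 0.0)))
        log_hr = -beta * k
        # delta method: d(logHR)/d beta = -k ; d(logHR)/d log sigma = beta*k
        grad = np.array([-k, beta * k])
        sub = cov_full[np.ix_([1, len(full) - 1], [1, len(full) - 1])]
        se_hr = float(np.sqrt(max(grad @ sub @ grad, 0.0)))
        effects["aft_per_allele"] = ContrastEffect(beta=beta, se=se_beta)
        effects["log_hr_per_allele"] = ContrastEffect(beta=log_hr, se=se_hr)
        p = effects["log_hr_per_allele"].wald_p
    else:
        p = float("nan")
    return AssocResult(
        variant_id=variant_id, model="weibull", effects=effects, p=p,
        n_used=int(t.size), converged=bool(res.success),
        intercepts={"mu": float(full[0]), "log_sigma": float(full[-1])},
        shape=k, loglik=float(-res.fun),
        df_model=int(full.size - (1 if fixed else 0)))
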