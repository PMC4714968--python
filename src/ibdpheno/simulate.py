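"""Synthetic IBD cohort generator.

Generates cohorts with the statistical structure the downstream analyses
assume, plus a ground-truth record, so every stage of the pipeline is
testable without any external data.  The generative model mirrors the fitted
models: three latent genetic sub-entities (ileal CD, colonic CD, UC) drawn
from a multinomial logit over per-sample linear predictors; genotypes
binomial in allele frequencies that may drift along latent structure axes;
ileocolonic (L3) disease assigned where the ileal and colonic predictors are
close, so it is genetically intermediate by construction; behaviour evolving
through exponential B1->B2->B3 progression with location-specific rates;
surgery/colectomy times Weibull with location/extent-dependent scale,
right-censored at follow-up; age at diagnosis normal with per-locus shifts;
missingness applied completely at random; and an optional rate of swapped
(misdiagnosed) CD/UC labels.

One global seed drives ordered sub-seeds per stage (genotypes, labels,
times, missingness), so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import (GenotypeMatrix, LocusGroup, PhenotypeTable, Variant,
                     age_band)

SUBTYPES = ("ilealCD", "colonicCD", "UC")


@dataclass
class SpecialLocus:
    """A tagged locus with its own effect triple (log-odds per allele)."""

    tag: str                      # NOD2 / MHC / MST1
    maf: float
    beta: tuple[float, float, float]   # (ileal, colonic, UC)
    age_beta: float = 0.0         # SD units per allele on age at diagnosis
    surgery_log_hr: float = 0.0   # log hazard ratio per allele, CD surgery
    extent_log_or: float = 0.0    # log OR per allele, E3 vs E1/E2 (UC)
    is_hla: bool = False


def _default_special_loci() -> list[SpecialLocus]:
    # effect scales follow the three genome-wide significant locus groups:
    # a large ileal-directed NOD2-like frameshift, an MHC-like colonic/UC
    # haplotype that also drives extensive UC, and an MST1-like age shift
    return [
        SpecialLocus(tag="NOD2", maf=0.024,
                     beta=(np.log(2.5), 0.0, -0.5),
                     age_beta=-0.16, surgery_log_hr=np.log(1.31)),
        SpecialLocus(tag="MHC", maf=0.116,
                     beta=(0.0, -np.log(0.45), 0.3),
                     extent_log_or=np.log(0.70), is_hla=True),
        SpecialLocus(tag="MST1", maf=0.28,
                     beta=(0.10, 0.05, 0.0), age_beta=-0.06),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study cohort."""

    n_samples: int = 30000
    n_background: int = 160
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: latent class base probabilities over (ilealCD, colonicCD, UC)
    subtype_base_probs: tuple[float, float, float] = (0.32, 0.25, 0.43)
    #: background per-locus ileal-vs-UC odds-ratio magnitude range; the upper
    #: end covers the stronger known susceptibility loci so the CD-vs-UC score
    #: acquires a realistic spread (raw SD near 0.85)
    background_or_range: tuple[float, float] = (1.05, 1.4)
    #: colonic effect as a fraction of the ileal effect (intermediacy)
    colonic_blend: float = 0.5
    special_loci: list[SpecialLocus] = field(default_factory=_default_special_loci)
    n_pcs_structural: int = 5
    pc_effect_on_freq: float = 0.08     # SD of per-axis logit-frequency loadings
    pc_effect_on_class: float = 0.05    # per-axis effect on class predictors
    #: L3 margin: CD sample is ileocolonic when |eta_ileal - eta_colonic| <= margin
    l3_margin: float = 0.40
    ibdu_rate: float = 0.0086
    age_model: tuple[float, float] = (28.0, 12.0)   # mean, SD in years
    #: B1->B2 hazards per year by location, and the common B2->B3 hazard
    progression_b1b2: dict = field(default_factory=lambda: {
        "L1": 0.105, "L3": 0.055, "L2": 0.040, "OTHER": 0.060})
    progression_b2b3: float = 0.10
    weibull_shape: float = 1.2
    #: Weibull scale (years) of CD surgery by location and UC colectomy by extent
    surgery_scale: dict = field(default_factory=lambda: {
        "L1": 8.0, "L3": 11.0, "L2": 19.0, "OTHER": 13.0})
    colectomy_scale: dict = field(default_factory=lambda: {
        "E3": 26.0, "E2": 55.0, "E1": 75.0, "OTHER": 55.0})
    followup_mean: float = 11.0
    #: MCAR missingness per field (defaults mirror the printed Missing rows)
    missing_rates: dict = field(default_factory=lambda: {
        "sex": 0.02, "age_at_diagnosis": 0.13, "family_history": 0.20,
        "smoking": 0.27, "location": 0.18, "behaviour": 0.18,
        "extent": 0.14, "surgery_event": 0.18})
    misdiagnosis_rate: float = 0.005
    n_sites: int = 10
    uk_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.subtype_base_probs, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("subtype_base_probs must lie on the simplex")
        if self.weibull_shape <= 0:
            raise ValueError("Weibull shape must be positive")
        for name in ("pc_effect_on_freq", "misdiagnosis_rate", "ibdu_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for k, v in self.missing_rates.items():
            if not (0 <= v <= 1):
                raise ValueError(f"missing rate for {k} out of [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each simulated cohort."""

    per_sample: pd.DataFrame     # latent subtype, etas, swap flag, true times
    effect_table: pd.DataFrame   # per-variant true (beta_ileal, beta_colonic, beta_UC)
    config: SimulationConfig

    def to_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False, na_rep="")


def _stage_rngs(seed: int, n: int = 8):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def build_effect_table(cfg: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-variant true effect triples and metadata.

    Background loci get an ileal-vs-UC log OR drawn uniformly (in log space)
    from the configured magnitude range with a random sign, a colonic effect
    equal to ``colonic_blend`` times the ileal one (placing colonic CD between
    ileal CD and UC by construction), and UC as the reference (0).
    """
    lo, hi = np.log(cfg.background_or_range[0]), np.log(cfg.background_or_range[1])
    rows = []
    for i in range(cfg.n_background):
        mag = rng.uniform(lo, hi)
        sign = rng.choice([-1.0, 1.0])
        u = sign * mag
        maf = rng.uniform(*cfg.maf_range)
        rows.append({"id": f"rs{i + 1:04d}", "locus_group": "OTHER",
                     "is_hla": i < 20,   # a slice of the panel is HLA-type like
                     "maf": maf, "beta_ileal": u,
                     "beta_colonic": cfg.colonic_blend * u, "beta_UC": 0.0,
                     "age_beta": 0.0, "surgery_log_hr": 0.0,
                     "extent_log_or": 0.0})
    for sp in cfg.special_loci:
        rows.append({"id": f"rs_{sp.tag}", "locus_group": sp.tag,
                     "is_hla": sp.is_hla, "maf": sp.maf,
                     "beta_ileal": sp.beta[0], "beta_colonic": sp.beta[1],
                     "beta_UC": sp.beta[2], "age_beta": sp.age_beta,
                     "surgery_log_hr": sp.surgery_log_hr,
                     "extent_log_or": sp.extent_log_or})
    return pd.DataFrame(rows)


def simulate_cohort(cfg: SimulationConfig
                    ) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Draw a full synthetic cohort; byte-identical for identical config."""
    (rng_geno, rng_label, rng_pheno, rng_times,
     rng_miss, rng_swap, rng_site, rng_fx) = _stage_rngs(cfg.seed)
    n = cfg.n_samples
    fx = build_effect_table(cfg, rng_fx)
    m = len(fx)

    # latent structure axes and structure-linked allele frequencies
    U = rng_geno.standard_normal((n, cfg.n_pcs_structural))
    loadings = rng_geno.normal(0.0, cfg.pc_effect_on_freq,
                               (cfg.n_pcs_structural, m))
    base_logit = np.log(fx["maf"].to_numpy() / (1 - fx["maf"].to_numpy()))
    p_ij = 1.0 / (1.0 + np.exp(-(base_logit[None, :] + U @ loadings)))
    G = rng_geno.binomial(2, p_ij).astype(float)

    # latent class from a multinomial logit over eta_k; the intercepts are
    # calibrated so the mean class probabilities hit subtype_base_probs
    # regardless of how much variance the genetic effects contribute
    B = fx[["beta_ileal", "beta_colonic", "beta_UC"]].to_numpy()
    gamma = cfg.pc_effect_on_class * np.array([1.0, -1.0, 0.0])[None, :]
    fixed = G @ B + U[:, :1] @ gamma
    base = np.asarray(cfg.subtype_base_probs)
    alpha = np.log(base)
    for _ in range(40):
        eta = alpha[None, :] + fixed
        ex = np.exp(eta - eta.max(axis=1, keepdims=True))
        probs = ex / ex.sum(axis=1, keepdims=True)
        alpha += np.log(base / probs.mean(axis=0))
    eta = alpha[None, :] + fixed
    ex = np.exp(eta - eta.max(axis=1, keepdims=True))
    probs = ex / ex.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng_label.random(n)
    cls = (u[:, None] > cum).sum(axis=1)   # 0 ileal, 1 colonic, 2 UC

    diagnosis = np.where(cls == 2, "UC", "CD").astype(object)
    # L3: genetically intermediate CD.  The band is taken on the genetic
    # (intercept-free) ileal-minus-colonic axis, centred at the CD median so
    # that ileocolonic disease sits between ileal and colonic by construction.
    d_gen = (eta[:, 0] - alpha[0]) - (eta[:, 1] - alpha[1])
    location = np.full(n, None, dtype=object)
    is_cd = cls != 2
    location[is_cd & (cls == 0)] = "L1"
    location[is_cd & (cls == 1)] = "L2"
    center = np.median(d_gen[is_cd]) if is_cd.any() else 0.0
    l3 = is_cd & (np.abs(d_gen - center) < cfg.l3_margin)
    location[l3] = "L3"

    # IBD-U: the configured fraction of colonic/UC samples closest to the
    # midpoint of the colonic-UC genetic axis (clinically indistinguishable
    # colonic IBD, genetically between colonic CD and UC)
    ibdu_pool = np.where(cls >= 1)[0]
    n_ibdu = int(round(cfg.ibdu_rate * n))
    if n_ibdu > 0 and ibdu_pool.size:
        d_cu = (eta[:, 1] - alpha[1]) - (eta[:, 2] - alpha[2])
        mid = 0.5 * (d_cu[cls == 1].mean() + d_cu[cls == 2].mean())
        gap = np.abs(d_cu[ibdu_pool] - mid)
        chosen = ibdu_pool[np.argsort(gap)[:n_ibdu]]
        diagnosis[chosen] = "IBDU"
        location[chosen] = None

    # UC extent: binary logit for extensive (E3) vs E1/E2
    ext_eta = 0.0 + G @ fx["extent_log_or"].to_numpy()
    p_e3 = 1.0 / (1.0 + np.exp(-ext_eta))
    is_uc = diagnosis == "UC"
    extent = np.full(n, None, dtype=object)
    e3 = rng_pheno.random(n) < p_e3
    extent[is_uc & e3] = "E3"
    non_e3 = is_uc & ~e3
    extent[non_e3] = np.where(rng_pheno.random(n)[non_e3] < 0.75, "E2", "E1")

    # age at diagnosis: normal with per-locus shifts in SD units
    mu_a, sd_a = cfg.age_model
    age_shift = G @ fx["age_beta"].to_numpy()
    age = mu_a + sd_a * (age_shift + rng_pheno.standard_normal(n))
    age = np.clip(age, 1.0, 85.0)

    followup = np.maximum(rng_times.exponential(cfg.followup_mean, n), 0.25)

    # demographics
    sex = np.where(rng_pheno.random(n) < 0.53, "female", "male").astype(object)
    smoking = rng_pheno.choice(["smoker", "ex", "never"], size=n,
                               p=[0.21, 0.20, 0.59]).astype(object)
    family = (rng_pheno.random(n) < 0.24)
    yob = np.round(2010.0 - age - rng_pheno.uniform(0, 15, n))

    site_idx = rng_site.integers(0, cfg.n_sites, n)
    n_uk = max(1, int(round(cfg.uk_fraction * cfg.n_sites)))
    site = np.array([f"site{j:02d}" for j in site_idx], dtype=object)
    country = np.where(site_idx < n_uk, "UK", "nonUK").astype(object)

    df = pd.DataFrame({
        "sample_id": [f"S{i:06d}" for i in range(n)],
        "diagnosis": diagnosis, "location": location,
        "upper_gi_L4": np.where(is_cd, rng_pheno.random(n) < 0.14, None),
        "behaviour": None, "perianal": np.where(
            is_cd, rng_pheno.random(n) < 0.2, None),
        "extent": extent, "age_at_diagnosis": age, "age_band": None,
        "sex": sex, "smoking": smoking, "family_history": family,
        "year_of_birth": yob, "site": site, "country": country,
        "followup_years": followup, "surgery_event": None,
        "surgery_time_years": None, "diagnosis_revised": None,
    })

    truth_df = pd.DataFrame({
        "sample_id": df["sample_id"],
        "latent_subtype": [SUBTYPES[c] for c in cls],
        "eta_ileal": eta[:, 0], "eta_colonic": eta[:, 1], "eta_UC": eta[:, 2],
        "swapped_label": False,
    })
    truth = TruthRecord(per_sample=truth_df, effect_table=fx, config=cfg)
    P = PhenotypeTable(df, strict=False)

    simulate_progression(P, truth, cfg, rng=rng_times)
    _simulate_surgery(P, truth, cfg, G, fx, rng=rng_times)

    if cfg.misdiagnosis_rate > 0:
        swap_seed = int(rng_swap.integers(0, 2**31 - 1))
        P, truth = spike_misdiagnosis(P, truth, cfg.misdiagnosis_rate,
                                      seed=swap_seed)

    _apply_missingness(P, cfg, rng_miss)

    variants = [Variant(id=r.id, chrom="1", pos=1000 + 100 * i,
                        locus_group=LocusGroup(r.locus_group),
                        is_hla=bool(r.is_hla))
                for i, r in enumerate(fx.itertuples())]
    gm = GenotypeMatrix(samples=list(df["sample_id"]), variants=variants,
                        dosages=G)
    return gm, P, truth


def simulate_progression(P: PhenotypeTable, truth: TruthRecord,
                         cfg: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Exponential B1->B2 and B2->B3 waiting times for CD samples.

    Rates are location-specific for the first transition (ileal disease
    progresses fastest).  Behaviour at last follow-up is written back into
    ``P``; the per-sample event log (true transition times) is returned and
    recorded in the truth table.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    df = P.df
    n = len(df)
    is_cd = (df["diagnosis"] == "CD").to_numpy()
    loc = df["location"].to_numpy(dtype=object)
    rate12 = np.array([cfg.progression_b1b2.get(l, 0.0) if l else 0.0
                       for l in loc])
    with np.errstate(divide="ignore"):
        t12 = np.where(rate12 > 0, rng.exponential(1.0, n) / np.where(
            rate12 > 0, rate12, 1.0), np.inf)
        t23 = (t12 + (rng.exponential(1.0, n) / cfg.progression_b2b3
                      if cfg.progression_b2b3 > 0 else np.inf))
    if cfg.progression_b2b3 <= 0:
        t23 = np.full(n, np.inf)
    fu = df["followup_years"].to_numpy(dtype=float)
    behaviour = np.where(t23 <= fu, "B3", np.where(t12 <= fu, "B2", "B1"))
    behaviour = behaviour.astype(object)
    behaviour[~is_cd] = None
    df["behaviour"] = behaviour
    log = pd.DataFrame({"sample_id": df["sample_id"],
                        "t_b1_to_b2": np.where(is_cd, t12, np.nan),
                        "t_b2_to_b3": np.where(is_cd, t23, np.nan)})
    truth.per_sample = truth.per_sample.drop(
        columns=[c for c in ("t_b1_to_b2", "t_b2_to_b3")
                 if c in truth.per_sample.columns])
    truth.per_sample = truth.per_sample.merge(log, on="sample_id")
    return log


def _simulate_surgery(P: PhenotypeTable, truth: TruthRecord,
                      cfg: SimulationConfig, G: np.ndarray,
                      fx: pd.DataFrame, rng: np.random.Generator) -> None:
    """Weibull surgery (CD) / colectomy (UC) times, right-censored."""
    df = P.df
    n = len(df)
    k = cfg.weibull_shape
    scale = np.full(n, np.nan)
    loc = df["location"].to_numpy(dtype=object)
    ext = df["extent"].to_numpy(dtype=object)
    cd = (df["diagnosis"] == "CD").to_numpy()
    uc = (df["diagnosis"] == "UC").to_numpy()
    for lcode, lam in cfg.surgery_scale.items():
        scale[cd & (loc == lcode)] = lam
    scale[cd & pd.isna(loc)] = np.mean(list(cfg.surgery_scale.values()))
    for ecode, lam in cfg.colectomy_scale.items():
        scale[uc & (ext == ecode)] = lam
    scale[uc & pd.isna(ext)] = np.mean(list(cfg.colectomy_scale.values()))
    # per-allele hazard ratio enters as an AFT shift: lambda *= HR^(-1/k)
    hr_shift = G @ fx["surgery_log_hr"].to_numpy()
    scale = scale * np.exp(-hr_shift / k)
    t_true = scale * rng.weibull(k, n)
    fu = df["followup_years"].to_numpy(dtype=float)
    has = ~np.isnan(t_true)
    event = has & (t_true <= fu)
    df["surgery_event"] = pd.array(np.where(has, event, None))
    df["surgery_time_years"] = np.where(
        has, np.minimum(t_true, fu), np.nan)
    truth.per_sample["t_surgery_true"] = t_true


def spike_misdiagnosis(P: PhenotypeTable, truth: TruthRecord, rate: float,
                       seed: int = 0) -> tuple[PhenotypeTable, TruthRecord]:
    """Swap a Bernoulli(rate) subset of CD/UC diagnoses.

    Swapped-to-CD samples become colonic (L2) with missing behaviour history
    re-coded to the nearest valid state; swapped-to-UC samples become
    extensive (E3).  Truth flags are updated; ``diagnosis_revised`` is left
    for downstream assignment (the re-phenotyping arm).
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    df = P.df.copy()
    tr = truth.per_sample.copy()
    eligible = df["diagnosis"].isin(["CD", "UC"]).to_numpy()
    swap = eligible & (rng.random(len(df)) < rate)
    was_cd = swap & (df["diagnosis"] == "CD").to_numpy()
    was_uc = swap & (df["diagnosis"] == "UC").to_numpy()
    df.loc[was_cd, "diagnosis"] = "UC"
    df.loc[was_cd, ["location", "behaviour", "upper_gi_L4", "perianal"]] = None
    df.loc[was_cd, "extent"] = "E3"
    df.loc[was_uc, "diagnosis"] = "CD"
    df.loc[was_uc, "extent"] = None
    df.loc[was_uc, "location"] = "L2"
    df.loc[was_uc, "behaviour"] = "B1"
    tr["swapped_label"] = tr["swapped_label"].to_numpy() | swap
    return (PhenotypeTable(df, strict=False),
            TruthRecord(per_sample=tr, effect_table=truth.effect_table,
                        config=truth.config))


def _apply_missingness(P: PhenotypeTable, cfg: SimulationConfig,
                       rng: np.random.Generator) -> None:
    df = P.df
    n = len(df)
    for col, rate in cfg.missing_rates.items():
        if rate <= 0 or col not in df.columns:
            continue
        hit = rng.random(n) < rate
        if pd.api.types.is_float_dtype(df[col]):
            df.loc[hit, col] = np.nan
        else:
            if df[col].dtype != object:
                df[col] = df[col].astype(object)
            df.loc[hit, col] = None
        if col == "surgery_event":
            df.loc[hit, "surgery_time_years"] = np.nan
        if col == "age_at_diagnosis":
            df.loc[hit, "age_band"] = None


def emulate_rephenotyping(P: PhenotypeTable, truth: TruthRecord,
                          sensitivity: float = 0.85,
                          false_doubt_rate: float = 0.08,
                          seed: int = 0) -> PhenotypeTable:
    """Assign diagnosis_revised flags as a masked re-phenotyping would.

    A truly swapped label raises doubt with probability ``sensitivity``; an
    unswapped one with the background ``false_doubt_rate``.
    """
    rng = np.random.default_rng(seed)
    df = P.df.copy()
    swapped = truth.per_sample.set_index("sample_id").loc[
        df["sample_id"], "swapped_label"].to_numpy()
    u = rng.random(len(df))
    revised = np.where(swapped, u < sensitivity, u < false_doubt_rate)
    df["diagnosis_revised"] = revised
    return PhenotypeTable(df, strict=False)
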