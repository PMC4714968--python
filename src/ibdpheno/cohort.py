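"""Cohort containers and I/O.

Genotypes live in a :class:`GenotypeMatrix` (samples x variants dosage matrix,
values in [0, 2], NaN for missing) with per-variant metadata; phenotypes in a
:class:`PhenotypeTable` wrapping a validated pandas DataFrame of Montreal
classification codes, demographics and follow-up.  Readers accept VCF (GT or
DS fields, via cyvcf2) or a plain dosage TSV; phenotypes are a TSV with a
controlled vocabulary.  ``compute_pcs`` produces genotype principal components
for population-structure adjustment and ``summarize_cohort`` the standard
per-diagnosis phenotype-distribution table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class LocusGroup(str, Enum):
    """Locus tags used for leave-out analyses and special-effect bookkeeping."""

    NOD2 = "NOD2"
    MHC = "MHC"
    MST1 = "MST1"
    OTHER = "OTHER"


DIAGNOSES = ("CD", "UC", "IBDU")
LOCATIONS = ("L1", "L2", "L3", "OTHER")
BEHAVIOURS = ("B1", "B2", "B3")
EXTENTS = ("E1", "E2", "E3", "OTHER")
SMOKING = ("smoker", "ex", "never")

#: Montreal age-at-diagnosis bands: A1 < 17, A2 17-40, A3 > 40 years.
AGE_BANDS = ("A1", "A2", "A3")

PHENOTYPE_COLUMNS = [
    "sample_id", "diagnosis", "location", "upper_gi_L4", "behaviour",
    "perianal", "extent", "age_at_diagnosis", "age_band", "sex", "smoking",
    "family_history", "year_of_birth", "site", "country", "followup_years",
    "surgery_event", "surgery_time_years", "diagnosis_revised",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class Variant:
    id: str
    chrom: str = "1"
    pos: int = 0
    ref: str = "A"
    alt: str = "G"
    maf: float = float("nan")
    locus_group: LocusGroup = LocusGroup.OTHER
    is_hla: bool = False


def age_band(age: float) -> str:
    """Montreal age band for an age at diagnosis in years."""
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return None
    if age < 17:
        return "A1"
    if age <= 40:
        return "A2"
    return "A3"


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with 0-2 dosages and NaN for missing."""

    samples: list[str]
    variants: list[Variant]
    dosages: np.ndarray  # float array, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate variant id(s): {dup}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"dosage out of [0, 2] at sample {self.samples[i]!r}, "
                f"variant {self.variants[j].id!r}: {self.dosages[i, j]}"
            )
        for j, v in enumerate(self.variants):
            v.maf = self._maf(self.dosages[:, j])

    @staticmethod
    def _maf(col: np.ndarray) -> float:
        ok = ~np.isnan(col)
        if not ok.any():
            return float("nan")
        p = float(col[ok].mean()) / 2.0
        return min(p, 1.0 - p)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def missingness(self) -> np.ndarray:
        """Per-variant missingness rate."""
        return np.isnan(self.dosages).mean(axis=0)

    def column(self, variant_id: str) -> np.ndarray:
        j = self.variant_ids.index(variant_id)
        return self.dosages[:, j]

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(i) for i in ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def imputed(self) -> np.ndarray:
        """Dosages with per-variant mean imputation of missing entries."""
        d = self.dosages.copy()
        means = np.nanmean(d, axis=0)
        nan_idx = np.where(np.isnan(d))
        d[nan_idx] = np.take(means, nan_idx[1])
        return d


@dataclass
class CovariateSet:
    """Named numeric covariate columns aligned with an ordered sample list."""

    samples: list[str]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if len(self.data) != len(self.samples):
            raise ValueError("covariate rows inconsistent with sample count")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


class PhenotypeTable:
    """Validated per-sample Montreal phenotype and demographic table.

    Montreal invariants: ``location``/``behaviour`` may be non-missing only for
    CD, ``extent`` only for UC; event times are nonnegative and bounded by
    follow-up.  ``strict=True`` raises on violations, ``strict=False`` nulls
    the offending cells.
    """

    def __init__(self, df: pd.DataFrame, strict: bool = True):
        df = df.copy().reset_index(drop=True)
        for col in PHENOTYPE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.df = df
        self._validate(strict)

    def _fail_or_null(self, strict, mask, col, msg):
        if not mask.any():
            return
        if strict:
            raise ValueError(f"{msg} (rows {list(self.df.index[mask][:5])})")
        self.df.loc[mask, col] = np.nan

    def _validate(self, strict: bool) -> None:
        df = self.df
        for col, vocab in [
            ("diagnosis", DIAGNOSES), ("location", LOCATIONS),
            ("behaviour", BEHAVIOURS), ("extent", EXTENTS),
            ("smoking", SMOKING), ("age_band", AGE_BANDS),
            ("sex", ("male", "female")),
        ]:
            vals = df[col].dropna()
            bad = sorted(set(vals) - set(vocab))
            if bad:
                raise ValueError(f"unknown {col} code(s): {bad}")
        not_cd = df["diagnosis"].notna() & (df["diagnosis"] != "CD")
        not_uc = df["diagnosis"].notna() & (df["diagnosis"] != "UC")
        for col in ("location", "behaviour", "upper_gi_L4", "perianal"):
            self._fail_or_null(
                strict, not_cd & df[col].notna(), col,
                f"{col} recorded for a non-CD case")
        self._fail_or_null(
            strict, not_uc & df["extent"].notna(), "extent",
            "extent recorded for a non-UC case")
        t, fu = df["surgery_time_years"], df["followup_years"]
        bad_t = t.notna() & ((t < 0) | (fu.notna() & (t > fu)))
        if bad_t.any():
            raise ValueError(
                f"surgery_time outside [0, followup] at rows "
                f"{list(df.index[bad_t][:5])}")
        # derive the age band wherever age is present
        age = df["age_at_diagnosis"]
        derived = age.map(lambda a: age_band(a) if pd.notna(a) else np.nan)
        df["age_band"] = df["age_band"].where(age.isna(), derived)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def subset(self, mask) -> "PhenotypeTable":
        return PhenotypeTable(self.df.loc[np.asarray(mask)], strict=False)


# ---------------------------------------------------------------------------
# readers / writers

def _gt_to_dosage(gt_types: np.ndarray) -> np.ndarray:
    # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
    out = np.full(gt_types.shape, np.nan)
    out[gt_types == 0] = 0.0
    out[gt_types == 1] = 1.0
    out[gt_types == 3] = 2.0
    return out


def read_genotypes(
    path: str | Path,
    dialect: str = "dosage_tsv",
    metadata: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a dosage TSV.

    VCF genotypes map 0/0, 0/1, 1/1 to dosages 0, 1, 2 and ./. to missing;
    a DS FORMAT field takes precedence over GT when present.  The dosage TSV
    dialect is ``sample_id<TAB>var1<TAB>...`` with one row per sample and
    ``NA`` for missing.  A variant-metadata sidecar TSV (id, chrom, pos, ref,
    alt, locus_group, is_hla) may be supplied for either dialect.
    """
    path = Path(path)
    if dialect == "vcf":
        gm = _read_vcf(path)
    elif dialect == "dosage_tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype={"id": str, "chrom": str})
        meta = meta.set_index("id")
        for v in gm.variants:
            if v.id in meta.index:
                row = meta.loc[v.id]
                v.chrom = str(row.get("chrom", v.chrom))
                v.pos = int(row.get("pos", v.pos))
                v.ref = str(row.get("ref", v.ref))
                v.alt = str(row.get("alt", v.alt))
                v.locus_group = LocusGroup(str(row.get("locus_group", "OTHER")))
                v.is_hla = bool(row.get("is_hla", False))
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, cols = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        alt = rec.ALT[0] if rec.ALT else "."
        variants.append(Variant(id=vid, chrom=str(rec.CHROM), pos=rec.POS,
                                ref=rec.REF, alt=alt))
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col[col < 0] = np.nan  # cyvcf2 encodes missing DS as negative fill
        else:
            col = _gt_to_dosage(np.asarray(rec.gt_types))
        cols.append(col)
    dos = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dos)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise FormatError("dosage TSV must start with a sample_id column")
    var_ids = list(df.columns[1:])
    samples = list(df["sample_id"])
    dos = df[var_ids].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    raw = df[var_ids].to_numpy()
    bad_token = np.isnan(dos) & (raw != "NA") & ~pd.isna(raw)
    if bad_token.any():
        i, j = map(int, np.argwhere(bad_token)[0])
        raise FormatError(
            f"unparseable dosage {raw[i, j]!r} at sample {samples[i]!r}, "
            f"variant {var_ids[j]!r}")
    return GenotypeMatrix(samples=samples,
                          variants=[Variant(id=v) for v in var_ids],
                          dosages=dos)


def write_genotypes(gm: GenotypeMatrix, path: str | Path,
                    dialect: str = "dosage_tsv") -> None:
    path = Path(path)
    if dialect == "dosage_tsv":
        df = pd.DataFrame(gm.dosages, columns=gm.variant_ids)
        df.insert(0, "sample_id", gm.samples)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")
    elif dialect == "vcf":
        _write_vcf(gm, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    # hard-call VCF: dosage 0/1/2 -> GT, anything fractional -> DS as well
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(gm.samples)]
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, v in enumerate(gm.variants):
        fields = []
        for d in gm.dosages[:, j]:
            if np.isnan(d):
                fields.append("./.:.")
            else:
                gt = gt_map.get(round(d, 6), "./.")
                fields.append(f"{gt}:{d:g}")
        lines.append("\t".join(
            [v.chrom, str(max(v.pos, 1)), v.id, v.ref, v.alt, ".", "PASS",
             ".", "GT:DS"] + fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_variant_metadata(gm: GenotypeMatrix, path: str | Path) -> None:
    rows = [{"id": v.id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
             "alt": v.alt, "locus_group": v.locus_group.value,
             "is_hla": v.is_hla} for v in gm.variants]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, strict: bool = True) -> PhenotypeTable:
    """Read and validate a phenotype TSV (see PHENOTYPE_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str,
                                            "country": str})
    for col in ("upper_gi_L4", "perianal", "family_history", "surgery_event",
                "diagnosis_revised"):
        if col in df.columns:
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False,
                 1: True, 0: False, 1.0: True, 0.0: False})
    return PhenotypeTable(df, strict=strict)


def write_phenotypes(P: PhenotypeTable, path: str | Path) -> None:
    P.df[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# principal components

def compute_pcs(gm: GenotypeMatrix, k: int = 5) -> CovariateSet:
    """Top-k genotype principal components for structure adjustment.

    Missing dosages are mean-imputed per variant, columns standardized, and
    the left singular vectors of the resulting matrix returned in decreasing
    singular-value order.  The sign of each PC is fixed by forcing its
    largest-magnitude sample loading positive, so results are deterministic.
    """
    if k >= min(gm.n_samples, gm.n_variants):
        raise ValueError("k must be < min(n_samples, n_variants)")
    d = gm.imputed()
    sd = d.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("no polymorphic variants")
    z = (d[:, poly] - d[:, poly].mean(axis=0)) / sd[poly]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pcs = u[:, :k]
    for i in range(k):
        if pcs[np.argmax(np.abs(pcs[:, i])), i] < 0:
            pcs[:, i] = -pcs[:, i]
    cols = {f"PC{i + 1}": pcs[:, i] for i in range(k)}
    return CovariateSet(samples=list(gm.samples), data=pd.DataFrame(cols))


# ---------------------------------------------------------------------------
# cohort summary (Table-1 style)

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CohortSummary:
    """Counts and integer percentages per diagnosis group and block.

    ``blocks[group][block]`` maps category -> (count, percent); percentages
    are computed among non-missing records (OTHER categories included in the
    denominator) and rounded half-up.  ``missing[group][block]`` is
    (count, percent-of-group-n).
    """

    group_n: dict
    blocks: dict
    missing: dict


_SUMMARY_BLOCKS = {
    "sex": (("male", "female"), None),
    "age_band": (("A1", "A2", "A3"), None),
    "family_history": ((True, False), None),
    "smoking": (SMOKING, None),
    "location": (LOCATIONS, "CD"),
    "extent": (EXTENTS, "UC"),
    "behaviour": (BEHAVIOURS, "CD"),
    "surgery_event": ((True, False), None),
}


def summarize_cohort(P: PhenotypeTable) -> CohortSummary:
    """Phenotype-distribution summary by diagnosis group (Table-1 style)."""
    if len(P) == 0:
        raise ValueError("empty phenotype table")
    df = P.df
    groups = {"CD": df[df["diagnosis"] == "CD"],
              "UC": df[df["diagnosis"] == "UC"],
              "IBD": df}
    blocks: dict = {}
    missing: dict = {}
    group_n = {g: len(d) for g, d in groups.items()}
    for g, d in groups.items():
        blocks[g], missing[g] = {}, {}
        for block, (cats, only) in _SUMMARY_BLOCKS.items():
            if only is not None and g != only:
                continue
            col = d[block]
            nonmiss = col.notna().sum()
            entry = {}
            for c in cats:
                cnt = int((col == c).sum())
                pct = _round_half_up(100.0 * cnt / nonmiss) if nonmiss else 0
                entry[c] = (cnt, pct)
            blocks[g][block] = entry
            n_miss = int(col.isna().sum())
            missing[g][block] = (
                n_miss, _round_half_up(100.0 * n_miss / len(d)) if len(d) else 0)
    return CohortSummary(group_n=group_n, blocks=blocks, missing=missing)


def summary_to_frame(summary: CohortSummary) -> pd.DataFrame:
    """Flatten a CohortSummary into a tidy DataFrame for writing."""
    rows = []
    for g, blks in summary.blocks.items():
        for block, entry in blks.items():
            for cat, (cnt, pct) in entry.items():
                rows.append({"group": g, "block": block, "category": str(cat),
                             "count": cnt, "percent": pct})
            m_cnt, m_pct = summary.missing[g][block]
            rows.append({"group": g, "block": block, "category": "missing",
                         "count": m_cnt, "percent": m_pct})
    return pd.DataFrame(rows)
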