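"""Cohort and genotype containers, validation and IO.

A :class:`Cohort` wraps a long-format visit table (one row per clinic
visit: subject id, sex, age in years, BMI in kg/m^2).  A
:class:`GenotypeTable` holds per-subject risk-allele dosages (0/1/2, NaN
for missing) for a named SNP panel.  Both are thin, validated wrappers
around :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "SEX_CODES",
    "SnpInfo",
    "Cohort",
    "GenotypeTable",
    "read_cohort",
    "write_cohort",
    "read_genotypes",
    "write_genotypes",
    "read_snp_info",
    "stratify_by_sex",
    "center_age",
]

#: canonical long-format dialect
CANONICAL_COLUMNS = {
    "subject_id": "subject_id",
    "sex": "sex",
    "age": "age_years",
    "bmi": "bmi",
}

#: accepted sex codes -> canonical {male, female}
SEX_CODES = {
    "m": "male",
    "male": "male",
    "1": "male",
    "f": "female",
    "female": "female",
    "2": "female",
}

AGE_RANGE = (0.0, 25.0)
BMI_RANGE = (5.0, 80.0)


class CohortValidationError(ValueError):
    """Raised when visit or genotype data violate the container invariants."""


@dataclass(frozen=True)
class SnpInfo:
    """A biallelic SNP: id, risk allele, risk-allele frequency.

    ``maf`` is the minor-allele frequency (in [0, 0.5]); ``risk_allele_freq``
    is the population frequency of the risk allele itself, which may exceed
    0.5 when the risk allele is the major allele (common among the adult
    BMI loci).  When ``risk_allele_freq`` is omitted it defaults to ``maf``.
    """

    snp_id: str
    risk_allele: str = "A"
    maf: float = 0.25
    risk_allele_freq: float | None = None

    def __post_init__(self):
        if self.risk_allele not in ("A", "C", "G", "T"):
            raise ValueError(f"risk allele must be A/C/G/T, got {self.risk_allele!r}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF must be in [0, 0.5], got {self.maf}")
        if self.risk_allele_freq is None:
            object.__setattr__(self, "risk_allele_freq", float(self.maf))
        elif not 0.0 <= self.risk_allele_freq <= 1.0:
            raise ValueError("risk_allele_freq must be in [0, 1]")
        raf = self.risk_allele_freq
        if abs(min(raf, 1 - raf) - self.maf) > 1e-9:
            raise ValueError(
                f"{self.snp_id}: risk_allele_freq {raf} inconsistent with MAF {self.maf}"
            )


def _normalize_sex(values: pd.Series) -> pd.Series:
    s = values.astype(str).str.strip().str.lower()
    unknown = sorted(set(s.unique()) - set(SEX_CODES))
    if unknown:
        raise CohortValidationError(f"unknown sex codes: {unknown}")
    return s.map(SEX_CODES)


class Cohort:
    """Validated long-format repeated BMI measures.

    The underlying frame has columns ``subject_id, sex, age_years, bmi``
    sorted by (subject, age).  Invariants enforced on construction:
    positive finite ages in (0, 25], BMI in (5, 80), constant sex per
    subject, no duplicate (subject, age) pairs.
    """

    def __init__(self, visits: pd.DataFrame, validate: bool = True):
        df = visits.loc[:, ["subject_id", "sex", "age_years", "bmi"]].copy()
        df["age_years"] = pd.to_numeric(df["age_years"])
        df["bmi"] = pd.to_numeric(df["bmi"])
        df["sex"] = _normalize_sex(df["sex"])
        df = df.sort_values(["subject_id", "age_years"], kind="mergesort")
        df = df.reset_index(drop=True)
        if validate:
            self._validate(df)
        self._df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        problems = []
        age, bmi = df["age_years"].to_numpy(), df["bmi"].to_numpy()
        bad_age = ~np.isfinite(age) | (age <= AGE_RANGE[0]) | (age > AGE_RANGE[1])
        bad_bmi = ~np.isfinite(bmi) | (bmi <= BMI_RANGE[0]) | (bmi >= BMI_RANGE[1])
        for idx in np.flatnonzero(bad_age):
            problems.append(f"row {idx}: age {age[idx]} outside (0, 25]")
        for idx in np.flatnonzero(bad_bmi):
            problems.append(f"row {idx}: bmi {bmi[idx]} outside (5, 80)")
        dup = df.duplicated(subset=["subject_id", "age_years"], keep=False)
        for idx in df.index[dup & ~df.duplicated(subset=["subject_id", "age_years"])]:
            rec = df.loc[idx]
            problems.append(
                f"duplicate (subject, age) pair: ({rec['subject_id']}, {rec['age_years']})"
            )
        n_sex = df.groupby("subject_id", sort=False)["sex"].nunique()
        for sid in n_sex.index[n_sex > 1]:
            problems.append(f"subject {sid}: sex not constant across visits")
        if problems:
            raise CohortValidationError(
                "invalid visit data:\n  " + "\n  ".join(problems[:50])
            )

    # -- container protocol ------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def subjects(self) -> np.ndarray:
        return self._df["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return self._df["subject_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self._df)

    def visits_per_subject(self) -> pd.Series:
        return self._df.groupby("subject_id", sort=False).size()

    def subset(self, subject_ids) -> "Cohort":
        keep = self._df["subject_id"].isin(list(subject_ids))
        return Cohort(self._df.loc[keep], validate=False)

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        return (
            f"<Cohort: {self.n_subjects} subjects, {self.n_visits} visits, "
            f"ages {self._df['age_years'].min():.2f}-{self._df['age_years'].max():.2f}>"
        )


class GenotypeTable:
    """Per-subject risk-allele dosages for a SNP panel.

    Wraps a frame indexed by subject id with one float column per SNP;
    entries are 0/1/2 or NaN (missing).  Missing dosages are preserved,
    never imputed.
    """

    def __init__(self, dosages: pd.DataFrame, snps: list[SnpInfo] | None = None):
        df = dosages.copy()
        df.index = df.index.astype(dosages.index.dtype)
        vals = df.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            rows, cols = np.nonzero(~ok)
            examples = [
                f"({df.index[r]}, {df.columns[c]}) = {vals[r, c]}"
                for r, c in zip(rows[:10], cols[:10])
            ]
            raise CohortValidationError(
                "dosages must be 0/1/2 or missing; offending cells: "
                + ", ".join(examples)
            )
        self._df = df.astype(float)
        if snps is not None:
            missing = [s.snp_id for s in snps if s.snp_id not in df.columns]
            if missing:
                raise CohortValidationError(f"SNPs absent from table: {missing}")
            self._df = self._df.loc[:, [s.snp_id for s in snps]]
        self.snps = snps

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def snp_ids(self) -> list[str]:
        return list(self._df.columns)

    def dosage(self, snp_id: str) -> pd.Series:
        if snp_id not in self._df.columns:
            raise KeyError(f"SNP {snp_id!r} not in table")
        return self._df[snp_id]

    def complete_cases(self, snp_ids=None) -> pd.Index:
        cols = list(snp_ids) if snp_ids is not None else list(self._df.columns)
        return self._df.index[self._df[cols].notna().all(axis=1)]

    def subset(self, subject_ids) -> "GenotypeTable":
        keep = self._df.index.intersection(pd.Index(subject_ids))
        return GenotypeTable(self._df.loc[keep], self.snps)

    def __len__(self) -> int:
        return len(self._df)


# ---------------------------------------------------------------------------
# IO


def read_cohort(path, dialect: dict | None = None) -> Cohort:
    """Read a long-format visit CSV into a validated :class:`Cohort`.

    ``dialect`` maps logical names (subject_id, sex, age, bmi) to the
    file's column names; the canonical header is
    ``subject_id,sex,age_years,bmi``.
    """
    colmap = dict(CANONICAL_COLUMNS)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise CohortValidationError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    renamed = df.rename(
        columns={
            colmap["subject_id"]: "subject_id",
            colmap["sex"]: "sex",
            colmap["age"]: "age_years",
            colmap["bmi"]: "bmi",
        }
    )
    for col in ("age_years", "bmi"):
        coerced = pd.to_numeric(renamed[col], errors="coerce")
        bad = renamed.index[coerced.isna() & renamed[col].notna()]
        if len(bad):
            raise CohortValidationError(
                f"{path}: non-numeric {col} in rows {list(bad[:20])}"
            )
        renamed[col] = coerced
    return Cohort(renamed)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical dialect CSV (round-trips with read_cohort)."""
    cohort.df.to_csv(path, index=False)


def read_genotypes(path, snps: list[SnpInfo] | None = None, missing_token: str = "") -> GenotypeTable:
    """Read a genotype dosage CSV: ``subject_id`` column + one column per SNP."""
    df = pd.read_csv(path, na_values=[missing_token, "NA"], keep_default_na=True)
    if "subject_id" not in df.columns:
        raise CohortValidationError(f"{path}: missing subject_id column")
    df = df.set_index("subject_id")
    return GenotypeTable(df, snps)


def write_genotypes(table: GenotypeTable, path) -> None:
    table.df.to_csv(path, index=True, index_label="subject_id")


def read_snp_info(path) -> list[SnpInfo]:
    """Read SNP metadata CSV ``snp_id,risk_allele,maf[,risk_allele_freq]``."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        raf = row.get("risk_allele_freq")
        out.append(
            SnpInfo(
                snp_id=str(row["snp_id"]),
                risk_allele=str(row["risk_allele"]),
                maf=float(row["maf"]),
                risk_allele_freq=None if pd.isna(raf) else float(raf),
            )
        )
    return out


# ---------------------------------------------------------------------------
# transforms


def stratify_by_sex(
    cohort: Cohort, genotypes: GenotypeTable | None = None
):
    """Split a cohort (and optionally its genotype table) into male/female strata.

    Returns ``(male, female)`` Cohorts, or
    ``((male, male_geno), (female, female_geno))`` when genotypes are given.
    The strata are disjoint and their union is the input.
    """
    df = cohort.df
    male = Cohort(df[df["sex"] == "male"], validate=False)
    female = Cohort(df[df["sex"] == "female"], validate=False)
    if genotypes is None:
        return male, female
    return (
        (male, genotypes.subset(male.subjects)),
        (female, genotypes.subset(female.subjects)),
    )


def center_age(ages, center: float = 8.0) -> np.ndarray:
    """Centred age covariate ``age - center`` (default 8 years, the mean
    follow-up age; a fixed constant keeps estimates comparable across
    strata and simulated cohorts)."""
    if not np.isfinite(center):
        raise ValueError("center must be finite")
    return np.asarray(ages, dtype=float) - float(center)
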