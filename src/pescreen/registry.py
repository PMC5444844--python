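"""Pregnancy-level registry data model: flags, ICD-10 mapping, CSV I/O.

A registry is a :class:`pandas.DataFrame` with one row per record (possibly
several rows per pregnancy before multiple-birth deduplication) and the
columns of :data:`REGISTRY_SCHEMA`: identifiers, a parity stratum, a binary
preeclampsia outcome, and thirteen binary exposure flags.  Raw fields
(maternal age, BMI, education years, ICD-10 code lists) may be carried
alongside and resolved into flags by :func:`dichotomize` /
:func:`apply_icd_codes`.

ICD-10 matching is by 3-character category prefix (registers store 4-5
character codes, so "O141" matches the O14 category); the antiphospholipid
code D68.6 is the one exception, matched at 4 characters because the D68
category is broader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

PRIMIPAROUS = "primiparous"
MULTIPAROUS = "multiparous"
PARITY_LEVELS = (PRIMIPAROUS, MULTIPAROUS)

#: Exposure flags, in canonical column order.
EXPOSURES = (
    "age_ge40",
    "low_education",
    "non_cohabiting",
    "dm",
    "hbp",
    "autoimmune",
    "ckd",
    "obesity",
    "previous_pe",
    "smoker",
    "multiple_pregnancy",
    "art",
    "gestational_diabetes",
)

#: Clinical risk factors counted by guideline-style rules (social covariates
#: and smoking excluded).
RISK_FACTORS = (
    "previous_pe", "ckd", "autoimmune", "dm", "hbp",
    "age_ge40", "obesity", "multiple_pregnancy", "art", "gestational_diabetes",
)

RAW_COLUMNS = ("maternal_age", "bmi", "education_years", "icd_codes")

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")


@dataclass(frozen=True)
class RegistrySchema:
    """Column layout of the registry CSV dialect."""

    id_columns: tuple[str, ...] = ("pregnancy_id", "mother_id")
    parity_column: str = "parity"
    outcome_column: str = "pe"
    exposure_columns: tuple[str, ...] = EXPOSURES
    raw_columns: tuple[str, ...] = RAW_COLUMNS

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (*self.id_columns, self.parity_column, self.outcome_column,
                *self.exposure_columns)


REGISTRY_SCHEMA = RegistrySchema()


class OutcomeFlags(NamedTuple):
    pe: bool
    gestational_htn: bool
    hbp_from_o16: bool


def _categories(codes: Iterable[str], context: str = "record") -> list[str]:
    cats = []
    for code in codes:
        code = str(code).strip().upper().replace(".", "")
        if not code:
            continue
        if not _ICD_RE.match(code):
            raise ValueError(f"malformed ICD-10 code {code!r} in {context}")
        cats.append(code)
    return cats


def map_icd_outcome(codes: Iterable[str], context: str = "record") -> OutcomeFlags:
    """Classify the hypertensive-disorder outcome from ICD-10 codes.

    PE/eclampsia is O14 or O15 and takes precedence: a record carrying both
    gestational hypertension (O13) and O14/O15 is classified as PE.  O11,
    O12 and O13 count as non-PE hypertensive disorders; unspecified
    maternal hypertension (O16) is treated as chronic hypertension.
    """
    cats = _categories(codes, context)
    pe = any(c[:3] in ("O14", "O15") for c in cats)
    gestational_htn = any(c[:3] == "O13" for c in cats)
    hbp_from_o16 = any(c[:3] == "O16" for c in cats)
    return OutcomeFlags(pe=pe, gestational_htn=gestational_htn, hbp_from_o16=hbp_from_o16)


_EXPOSURE_CATEGORIES = {
    "hbp": {"I10", "I11", "I12", "I13", "I14", "I15", "O16"},
    "dm": {"E10", "E11", "E12", "E13", "E14"},
    "ckd": {"N18", "N19"},
    "autoimmune": {"M32", "M05", "M06"},
    "gestational_diabetes": {"O24"},
}


def map_icd_exposures(codes: Iterable[str], context: str = "record") -> dict[str, bool]:
    """Disease-exposure flags from ICD-10 codes.

    Chronic hypertension I10-I15 (plus O16), diabetes mellitus E10-E14,
    chronic kidney disease N18/N19, autoimmune disease M32/M05/M06 together
    with antiphospholipid syndrome D68.6, gestational diabetes O24.
    """
    cats = _categories(codes, context)
    flags = {name: any(c[:3] in members for c in cats)
             for name, members in _EXPOSURE_CATEGORIES.items()}
    flags["autoimmune"] = flags["autoimmune"] or any(c.startswith("D686") for c in cats)
    return flags


def apply_icd_codes(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve an ``icd_codes`` column (';'-separated) into outcome/exposure flags.

    Existing flag columns are OR-ed with the code-derived flags; the ``pe``
    outcome and code-derived disease exposures are created if absent.
    """
    if "icd_codes" not in df.columns:
        return df
    df = df.copy()
    split = [
        [] if (isinstance(v, float) and np.isnan(v)) or v is None or v == ""
        else str(v).split(";")
        for v in df["icd_codes"]
    ]
    outcomes = [map_icd_outcome(codes, context=f"row {i}") for i, codes in enumerate(split)]
    exposures = [map_icd_exposures(codes, context=f"row {i}") for i, codes in enumerate(split)]
    pe = pd.Series([o.pe for o in outcomes], index=df.index)
    df["pe"] = pe | df["pe"].astype(bool) if "pe" in df.columns else pe
    for name in _EXPOSURE_CATEGORIES:
        derived = pd.Series([e[name] for e in exposures], index=df.index)
        df[name] = derived | df[name].astype(bool) if name in df.columns else derived
    return df


def dichotomize(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve raw continuous fields into binary flags.

    age >= 40 years -> ``age_ge40``; BMI >= 30 kg/m2 -> ``obesity``;
    <= 11 years of formal education -> ``low_education``.  Existing flag
    columns are left untouched; negative ages or BMIs are rejected.
    """
    df = df.copy()
    rules = {
        "age_ge40": ("maternal_age", lambda s: s >= 40),
        "obesity": ("bmi", lambda s: s >= 30),
        "low_education": ("education_years", lambda s: s <= 11),
    }
    for flag, (raw, fn) in rules.items():
        if flag in df.columns or raw not in df.columns:
            continue
        values = pd.to_numeric(df[raw])
        if raw in ("maternal_age", "bmi") and (values < 0).any():
            bad = df.index[values < 0][0]
            raise ValueError(f"negative {raw} at row {bad}")
        df[flag] = fn(values)
    return df


def validate(df: pd.DataFrame, schema: RegistrySchema = REGISTRY_SCHEMA,
             allow_shared_pregnancy_id: bool = False) -> pd.DataFrame:
    """Check registry invariants; returns the frame with canonical dtypes.

    Enforces: all required columns present and non-missing; parity levels
    valid; previous PE only in multiparous records; pregnancy_id unique
    unless multiple-birth rows are expected.
    """
    missing = [c for c in schema.required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"registry is missing required columns: {missing}")
    out = df.copy()
    flag_cols = (schema.outcome_column, *schema.exposure_columns)
    for col in flag_cols:
        if out[col].isna().any():
            raise ValueError(f"missing values in required column {col!r}")
        out[col] = out[col].astype(bool)
    parity = out[schema.parity_column]
    bad = ~parity.isin(PARITY_LEVELS)
    if bad.any():
        raise ValueError(f"invalid parity values: {sorted(parity[bad].unique())}")
    offending = out["previous_pe"] & (parity == PRIMIPAROUS)
    if offending.any():
        raise ValueError(
            f"previous_pe=True in primiparous record(s) "
            f"{out.loc[offending, 'pregnancy_id'].tolist()[:5]}")
    if not allow_shared_pregnancy_id and out["pregnancy_id"].duplicated().any():
        dup = out.loc[out["pregnancy_id"].duplicated(), "pregnancy_id"].iloc[0]
        raise ValueError(f"duplicate pregnancy_id {dup!r}; "
                         "run select_one_per_pregnancy first")
    return out


def _select_one_per(df: pd.DataFrame, key: str, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    shuffled = df.iloc[order]
    kept = shuffled[~shuffled[key].duplicated()]
    return kept.sort_index()


def select_one_per_pregnancy(df: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep one randomly chosen record per pregnancy_id (multiple births)."""
    return _select_one_per(df, "pregnancy_id", seed)


def select_one_per_mother(df: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep one randomly chosen record per mother_id (cluster-independent subset)."""
    return _select_one_per(df, "mother_id", seed)


_TRUE = {"1", "true", "TRUE", "True"}
_FALSE = {"0", "false", "FALSE", "False"}


def _parse_bool(value: str, column: str) -> bool:
    s = str(value).strip()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"unparseable boolean {value!r} in column {column!r}")


def read_registry(path, schema: RegistrySchema = REGISTRY_SCHEMA) -> pd.DataFrame:
    """Read a registry CSV, accepting 0/1/true/false boolean encodings."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema.required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"registry CSV is missing required columns: {missing}")
    out = pd.DataFrame(index=df.index)
    for col in schema.id_columns:
        out[col] = df[col].astype(str)
    out[schema.parity_column] = df[schema.parity_column].astype(str)
    for col in (schema.outcome_column, *schema.exposure_columns):
        out[col] = df[col].map(lambda v, c=col: _parse_bool(v, c)).astype(bool)
    for col in schema.raw_columns:
        if col in df.columns:
            out[col] = df[col] if col == "icd_codes" else pd.to_numeric(
                df[col].replace("", np.nan))
    return validate(out, schema, allow_shared_pregnancy_id=True)


def write_registry(df: pd.DataFrame, path, schema: RegistrySchema = REGISTRY_SCHEMA) -> None:
    """Write a registry CSV with booleans canonicalized to 0/1."""
    out = pd.DataFrame(index=df.index)
    for col in schema.required_columns:
        out[col] = df[col]
    for col in schema.raw_columns:
        if col in df.columns:
            out[col] = df[col]
    for col in (schema.outcome_column, *schema.exposure_columns):
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False)
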