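"""Guideline-style high-risk rules and forest-guided combination subgroups.

Three recreated guideline definitions of "high risk of preeclampsia":

* ``any_listed`` — at least one listed risk factor (major or moderate);
* ``one_major_or_two_moderate`` — NICE-style: one major factor or at
  least two moderate ones;
* ``one_major_incl_multiple`` — WHO-style: one major factor, with
  multiple pregnancy promoted to the major tier.

Major factors: previous preeclampsia, chronic kidney disease, autoimmune
disease, diabetes mellitus, chronic hypertension.  Moderate factors:
age >= 40, obesity, multiple pregnancy, ART conception, gestational
diabetes.  Within a parity stratum, parity itself is the stratifier and
never counted.

Combination subgroups follow exact-match semantics: a record belongs to
the subgroup ``(1, 0, 1, 1)`` over variables (A, B, C, D) only if its
flags equal that mask exactly; the reference is the all-false mask, and
discriminatory accuracy of each subgroup is computed against the whole
stratum.  Adjusted odds ratios come from one logistic fit per stratum
with all combination indicators plus the social covariates (smoking, low
education, non-cohabiting).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .accuracy import build_contingency, da_summary, rule_in_out_flags
from .glm import fit_logistic

MAJOR_FACTORS = ("previous_pe", "ckd", "autoimmune", "dm", "hbp")
MODERATE_FACTORS = ("age_ge40", "obesity", "multiple_pregnancy", "art",
                    "gestational_diabetes")

SOCIAL_COVARIATES = ("smoker", "low_education", "non_cohabiting")

RULE_KINDS = ("any_listed", "one_major_or_two_moderate", "one_major_incl_multiple")


@dataclass(frozen=True)
class RiskRule:
    """A named high-risk predicate over major/moderate factor sets."""

    name: str
    kind: str
    major: tuple[str, ...] = MAJOR_FACTORS
    moderate: tuple[str, ...] = MODERATE_FACTORS

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if set(self.major) & set(self.moderate):
            raise ValueError("major and moderate factor sets must be disjoint")


GUIDELINE_RULES = (
    RiskRule("any_risk", "any_listed"),
    RiskRule("one_major_or_two_moderate", "one_major_or_two_moderate"),
    RiskRule("one_major_incl_multiple", "one_major_incl_multiple"),
)


def classify(rule: RiskRule, records: pd.DataFrame) -> pd.Series:
    """Vectorized high-risk indicator for every record."""
    for col in (*rule.major, *rule.moderate):
        if col not in records.columns:
            raise KeyError(f"rule {rule.name!r} references unknown exposure {col!r}")
    n_major = records[list(rule.major)].astype(bool).sum(axis=1)
    n_moderate = records[list(rule.moderate)].astype(bool).sum(axis=1)
    if rule.kind == "any_listed":
        flagged = (n_major + n_moderate) >= 1
    elif rule.kind == "one_major_or_two_moderate":
        flagged = (n_major >= 1) | (n_moderate >= 2)
    else:  # one_major_incl_multiple
        flagged = (n_major >= 1) | records["multiple_pregnancy"].astype(bool)
    return flagged.rename(rule.name)


def risk_factor_count(records: pd.DataFrame,
                      factors: tuple[str, ...] = MAJOR_FACTORS + MODERATE_FACTORS
                      ) -> pd.Series:
    """Number of present clinical risk factors per record.

    Previous PE cannot occur in primiparous records (validation enforces
    it), so primiparous counts never include it.
    """
    return records[list(factors)].astype(bool).sum(axis=1).rename("n_risk_factors")


@dataclass
class SubgroupTable:
    """Per-combination accuracy rows plus the reference-cell size."""

    variables: tuple[str, ...]
    rows: pd.DataFrame
    reference_n: int
    stratum_n: int


def _combination_key(mask: tuple[int, ...]) -> str:
    return "".join(str(b) for b in mask)


def subgroup_da(records: pd.DataFrame, variables: tuple[str, ...],
                outcome: str = "pe",
                covariates: tuple[str, ...] = SOCIAL_COVARIATES,
                clusters: str | None = "mother_id") -> SubgroupTable:
    """Exact-match combination subgroup accuracy within one parity stratum.

    Every non-reference bitmask over ``variables`` becomes a marker
    ("record matches exactly this combination"), evaluated against the
    full stratum; adjusted ORs vs the all-false reference come from a
    single logistic fit with one indicator per observed combination plus
    the social covariates.  Combinations with n = 0 are emitted with null
    statistics.
    """
    parities = records["parity"].unique()
    if len(parities) != 1:
        raise ValueError("subgroup_da expects a single parity stratum")
    missing = [v for v in variables if v not in records.columns]
    if missing:
        raise KeyError(f"unknown subgroup variables: {missing}")

    flags = records[list(variables)].astype(bool).to_numpy()
    y = records[outcome].astype(bool).to_numpy()
    weights = 1 << np.arange(len(variables))[::-1]
    codes = flags.astype(int) @ weights  # mask as big-endian integer

    masks = [m for m in product((0, 1), repeat=len(variables)) if any(m)]
    # combinations whose indicator is estimable (some cases AND some controls);
    # all-case or all-control cells would separate the likelihood
    estimable = []
    for m in masks:
        in_cell = codes == int(np.dot(m, weights))
        if in_cell.any() and 0 < y[in_cell].sum() < in_cell.sum():
            estimable.append(m)

    # one adjusted fit: indicator per estimable combination + social covariates
    X = pd.DataFrame(index=records.index)
    for mask in estimable:
        X[f"combo_{_combination_key(mask)}"] = (codes == int(np.dot(mask, weights))).astype(float)
    for cov in covariates:
        X[cov] = records[cov].astype(float)
    groups = records[clusters] if clusters is not None and clusters in records.columns else None
    fit = fit_logistic(X, y.astype(float), clusters=groups)
    or_table = fit.odds_ratios(robust=True)

    rows = []
    for mask in masks:
        marker = codes == int(np.dot(mask, weights))
        n = int(marker.sum())
        row: dict = {"combination": _combination_key(mask), "n": n}
        for var, bit in zip(variables, mask):
            row[var] = bit
        if n == 0:
            row.update({k: np.nan for k in
                        ("ar", "af", "tpf", "fpf", "lr_pos", "lr_pos_lo", "lr_pos_hi",
                         "lr_neg", "or_adj", "or_adj_lo", "or_adj_hi")})
            row["lr_class"] = "none"
        else:
            da = da_summary(build_contingency(marker, y))
            name = f"combo_{_combination_key(mask)}"
            adj = (or_table.loc[name] if name in or_table.index
                   else pd.Series({"or": np.nan, "lo": np.nan, "hi": np.nan}))
            row.update({
                "ar": da.ar.value, "af": da.af.value,
                "tpf": da.tpf.value, "fpf": da.fpf.value,
                "lr_pos": da.lr_pos.value,
                "lr_pos_lo": da.lr_pos.lo, "lr_pos_hi": da.lr_pos.hi,
                "lr_neg": da.lr_neg.value,
                "or_adj": adj["or"], "or_adj_lo": adj["lo"], "or_adj_hi": adj["hi"],
                "lr_class": "/".join(sorted(rule_in_out_flags(da))),
            })
        rows.append(row)
    table = pd.DataFrame(rows)
    reference_n = int((codes == 0).sum())
    return SubgroupTable(variables=tuple(variables), rows=table,
                         reference_n=reference_n, stratum_n=len(records))
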