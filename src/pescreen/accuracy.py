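"""Discriminatory accuracy of a binary marker for a binary outcome.

Everything derives from a 2x2 contingency table (marker vs outcome):

======================  ==========================================
statistic               definition
======================  ==========================================
AR   (absolute risk)    tp / (tp + fp)            — PPV, in %
AF   (attributable risk) AR - fn / (fn + tn)      — risk difference, % points
TPF  (sensitivity)      tp / (tp + fn)            — in %
FPF  (1 - specificity)  fp / (fp + tn)            — in %
LR+                     TPF / FPF
LR-                     (1 - TPF) / (1 - FPF)
OR   (crude)            (tp * tn) / (fp * fn)  ==  LR+ / LR-
======================  ==========================================

Screening convention: LR+ > 10 rules the disease in, LR- < 0.2 rules it
out; LR+ in [5, 10] is moderate, [2, 5) small.

Confidence intervals: Wilson score for proportions, log (Simel-type)
intervals for likelihood ratios, Woolf log interval for the odds ratio.
With empty cells the point estimate is reported as-is (``inf``/``nan``
sentinels where undefined); the interval alone uses a 0.5 continuity
correction.  Percentages are carried in percent, matching the usual
presentation of screening tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

Z95 = 1.959963984540054  # two-sided 95 % normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of a binary marker cross-classified with the outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_outcome(self) -> int:
        return self.tp + self.fn

    @property
    def n_marker(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a 95 % confidence interval (nan bounds = omitted)."""

    value: float
    lo: float = math.nan
    hi: float = math.nan


@dataclass(frozen=True)
class DiagnosticAccuracy:
    """Full accuracy summary for one marker; percentages are in percent."""

    ar: Estimate
    ar_unexposed: Estimate
    af: Estimate
    tpf: Estimate
    fpf: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    or_crude: Estimate
    table: ContingencyTable


def build_contingency(marker, outcome) -> ContingencyTable:
    """Cross-tabulate aligned boolean vectors into a ContingencyTable."""
    marker = np.asarray(marker, dtype=bool)
    outcome = np.asarray(outcome, dtype=bool)
    if marker.shape != outcome.shape or marker.ndim != 1:
        raise ValueError("marker and outcome must be equal-length 1-D vectors")
    tp = int(np.sum(marker & outcome))
    fp = int(np.sum(marker & ~outcome))
    fn = int(np.sum(~marker & outcome))
    tn = int(np.sum(~marker & ~outcome))
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    if nobs == 0:
        return (math.nan, math.nan)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _proportion_estimate(count: int, nobs: int, scale: float = 100.0) -> Estimate:
    value = _ratio(count, nobs)
    lo, hi = _wilson(count, nobs)
    return Estimate(value * scale, lo * scale, hi * scale)


def _lr_ci(ct: ContingencyTable, positive: bool) -> tuple[float, float]:
    # log-method interval; 0.5 continuity correction when any cell is empty
    tp, fp, fn, tn = ct.tp, ct.fp, ct.fn, ct.tn
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    n1, n0 = tp + fn, fp + tn
    sens, spec = tp / n1, tn / n0
    if positive:
        lr = sens / (1 - spec)
        var = fn / (n1 * tp) + tn / (n0 * fp)
    else:
        lr = (1 - sens) / spec
        var = tp / (n1 * fn) + fp / (n0 * tn)
    half = Z95 * math.sqrt(var)
    return lr * math.exp(-half), lr * math.exp(half)


def _or_ci(ct: ContingencyTable) -> tuple[float, float]:
    tp, fp, fn, tn = ct.tp, ct.fp, ct.fn, ct.tn
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    log_or = math.log(tp * tn / (fp * fn))
    half = Z95 * math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    return math.exp(log_or - half), math.exp(log_or + half)


def da_summary(ct: ContingencyTable) -> DiagnosticAccuracy:
    """All discriminatory-accuracy statistics, with 95 % CIs."""
    tp, fp, fn, tn = ct.tp, ct.fp, ct.fn, ct.tn
    n1, n0 = tp + fn, fp + tn

    ar = _proportion_estimate(tp, tp + fp)
    ar_unexposed = _proportion_estimate(fn, fn + tn)
    tpf = _proportion_estimate(tp, n1)
    fpf = _proportion_estimate(fp, n0)

    af_value = ar.value - ar_unexposed.value
    # variance of a difference of two independent binomial proportions
    if tp + fp > 0 and fn + tn > 0:
        p1, p0 = tp / (tp + fp), fn / (fn + tn)
        se = math.sqrt(p1 * (1 - p1) / (tp + fp) + p0 * (1 - p0) / (fn + tn)) * 100
        af = Estimate(af_value, af_value - Z95 * se, af_value + Z95 * se)
    else:
        af = Estimate(af_value)

    lr_pos_val = _ratio(_ratio(tp, n1), _ratio(fp, n0))
    lr_neg_val = _ratio(_ratio(fn, n1), _ratio(tn, n0))
    or_val = _ratio(tp * tn, fp * fn)

    lr_pos = Estimate(lr_pos_val, *_lr_ci(ct, positive=True))
    lr_neg = Estimate(lr_neg_val, *_lr_ci(ct, positive=False))
    or_crude = Estimate(or_val, *_or_ci(ct))
    return DiagnosticAccuracy(ar=ar, ar_unexposed=ar_unexposed, af=af, tpf=tpf,
                              fpf=fpf, lr_pos=lr_pos, lr_neg=lr_neg,
                              or_crude=or_crude, table=ct)


def rule_in_out_flags(da: DiagnosticAccuracy) -> frozenset[str]:
    """Screening-strength labels for a marker's likelihood ratios.

    ``rule_in`` (LR+ > 10) and ``rule_out`` (LR- < 0.2) can co-occur;
    ``moderate`` is LR+ in [5, 10], ``small`` LR+ in [2, 5).  An empty set
    is reported as {"none"}.
    """
    flags: set[str] = set()
    lp, ln = da.lr_pos.value, da.lr_neg.value
    if lp > 10:
        flags.add("rule_in")
    elif 5 <= lp <= 10:
        flags.add("moderate")
    elif 2 <= lp < 5:
        flags.add("small")
    if ln < 0.2:
        flags.add("rule_out")
    return frozenset(flags) if flags else frozenset({"none"})


def format_pct(value: float) -> str:
    """Display rule for tiny percentages: values below 0.05 print as "~0"."""
    if math.isnan(value):
        return "NA"
    if 0 <= value < 0.05:
        return "~0"
    if value > 99.95 and value <= 100:
        return "~100"
    return f"{value:.1f}"
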