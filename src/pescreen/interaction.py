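"""Additive and multiplicative interaction between two binary factors.

For a stratifier i (1 = primiparous) and a risk factor j, the logistic
model with main effects and one product term yields odds ratios against
the doubly-unexposed cell: OR10 (stratifier only), OR01 (factor only) and
OR11 (both).  Two interaction scales follow:

* multiplicative — ratio of ORs = OR11 / (OR10 x OR01), which equals the
  exponentiated product-term coefficient; its CI comes straight from that
  coefficient's standard error;
* additive — interaction contrast ratio ICR (also called RERI) =
  OR11 - OR10 - OR01 + 1, with a delta-method CI on the OR scale built
  from the coefficient covariance matrix (robust when clusters given).

A scale shows significant interaction when its CI excludes the null
(1 for the ratio of ORs, 0 for the ICR); the sign of the point estimate
then classifies the interaction as positive or negative.  The two scales
may legitimately disagree in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accuracy import Estimate
from .glm import Z95, LogisticFit, fit_logistic


@dataclass(frozen=True)
class InteractionEstimate:
    """Joint-effect odds ratios and both interaction scales for one factor."""

    factor: str
    stratifier: str
    or11: float
    or10: float
    or01: float
    ratio_of_or: Estimate
    icr: Estimate
    fit: LogisticFit


def interaction_fit(data: pd.DataFrame, factor: str, stratifier: str,
                    outcome: str = "pe", covariates: tuple[str, ...] = (),
                    clusters: str | None = None) -> InteractionEstimate:
    """Fit the one-product-term logistic model and derive both scales."""
    cells = pd.crosstab(data[stratifier].astype(bool), data[factor].astype(bool))
    for i in (False, True):
        for j in (False, True):
            if cells.reindex(index=[i], columns=[j], fill_value=0).iloc[0, 0] == 0:
                raise ValueError(
                    f"empty cell ({stratifier}={int(i)}, {factor}={int(j)}): "
                    "interaction model is inestimable")

    X = pd.DataFrame({
        stratifier: data[stratifier].astype(float),
        factor: data[factor].astype(float),
        "product": (data[stratifier].astype(bool) & data[factor].astype(bool)).astype(float),
    })
    for cov in covariates:
        X[cov] = data[cov].astype(float)
    groups = data[clusters] if clusters is not None else None
    fit = fit_logistic(X, data[outcome], clusters=groups)

    b = fit.params
    b1, b2, b3 = b[stratifier], b[factor], b["product"]
    or10, or01, or11 = np.exp(b1), np.exp(b2), np.exp(b1 + b2 + b3)

    se3 = fit.se(robust=True)["product"]
    ratio = Estimate(float(np.exp(b3)), float(np.exp(b3 - Z95 * se3)),
                     float(np.exp(b3 + Z95 * se3)))

    icr_val = or11 - or10 - or01 + 1
    # delta method on the OR scale: gradient of OR11-OR10-OR01+1
    # w.r.t. (b1, b2, b3)
    grad = np.array([or11 - or10, or11 - or01, or11])
    cov = fit.cov_robust.loc[[stratifier, factor, "product"],
                             [stratifier, factor, "product"]].to_numpy()
    se_icr = float(np.sqrt(grad @ cov @ grad))
    icr = Estimate(float(icr_val), float(icr_val - Z95 * se_icr),
                   float(icr_val + Z95 * se_icr))
    return InteractionEstimate(factor=factor, stratifier=stratifier,
                               or11=float(or11), or10=float(or10), or01=float(or01),
                               ratio_of_or=ratio, icr=icr, fit=fit)


def _classify(est: Estimate, null: float) -> str:
    if est.lo > null:
        return "positive"
    if est.hi < null:
        return "negative"
    if est.value == null:
        return "absent"
    return "nonsignificant"


def classify_interaction(est: InteractionEstimate) -> dict[str, str]:
    """Per-scale labels: positive / negative / absent / nonsignificant."""
    return {
        "multiplicative": _classify(est.ratio_of_or, null=1.0),
        "additive": _classify(est.icr, null=0.0),
    }


def interaction_screen(data: pd.DataFrame, factors: tuple[str, ...],
                       stratifier: str, outcome: str = "pe",
                       covariates: tuple[str, ...] = (),
                       clusters: str | None = None) -> pd.DataFrame:
    """One-row-per-factor interaction report on both scales."""
    rows = []
    for factor in factors:
        est = interaction_fit(data, factor, stratifier, outcome=outcome,
                              covariates=covariates, clusters=clusters)
        labels = classify_interaction(est)
        rows.append({
            "factor": factor,
            "or11": est.or11, "or10": est.or10, "or01": est.or01,
            "ratio_of_or": est.ratio_of_or.value,
            "ratio_lo": est.ratio_of_or.lo, "ratio_hi": est.ratio_of_or.hi,
            "multiplicative": labels["multiplicative"],
            "icr": est.icr.value, "icr_lo": est.icr.lo, "icr_hi": est.icr.hi,
            "additive": labels["additive"],
        })
    return pd.DataFrame(rows)
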