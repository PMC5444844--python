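"""Logistic modelling layer: fits with cluster-robust variance, backward
elimination, ROC/AUC, and predicted-probability centile rules.

Fitting is maximum likelihood (iteratively reweighted least squares via
``statsmodels``); the robust covariance is the CR0 cluster sandwich with
scores summed over mother clusters and no small-sample correction —
appropriate here because cluster counts are large.  Wald tests on the
robust covariance drive the backward-elimination screen at alpha = 0.1.

AUC is the Mann-Whitney rank statistic (tie-corrected); the sensitivity at
a fixed false-positive fraction reads the empirical ROC step function.
Centile rules dichotomize predicted probabilities at the nearest-rank
stratum percentile with a strict ``>`` comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata


Z95 = 1.959963984540054


class SeparationError(RuntimeError):
    """Raised when the likelihood diverges (perfectly separated data)."""


@dataclass
class LogisticFit:
    """A fitted logistic model with model-based and cluster-robust variance."""

    params: pd.Series
    cov_model: pd.DataFrame
    cov_robust: pd.DataFrame
    llf: float
    aic: float
    nobs: int
    converged: bool
    n_clusters: int | None = None

    @property
    def names(self) -> list[str]:
        return list(self.params.index)

    def se(self, robust: bool = True) -> pd.Series:
        cov = self.cov_robust if robust else self.cov_model
        return pd.Series(np.sqrt(np.diag(cov)), index=self.params.index)

    def wald_p(self, robust: bool = True) -> pd.Series:
        z = self.params / self.se(robust)
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.params.index)

    def odds_ratios(self, robust: bool = True) -> pd.DataFrame:
        """OR point estimates with 95 % Wald CIs (per coefficient)."""
        se = self.se(robust)
        return pd.DataFrame({
            "or": np.exp(self.params),
            "lo": np.exp(self.params - Z95 * se),
            "hi": np.exp(self.params + Z95 * se),
            "p": self.wald_p(robust),
        })

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = _with_intercept(X)[self.names]
        lp = X.to_numpy(dtype=float) @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-lp))


def _with_intercept(X: pd.DataFrame) -> pd.DataFrame:
    if "const" not in X.columns:
        X = sm.add_constant(X.astype(float), has_constant="add")
    return X.astype(float)


def fit_logistic(X: pd.DataFrame, y, clusters=None) -> LogisticFit:
    """Maximum-likelihood logistic fit.

    ``X`` is the design (an intercept column ``const`` is added if absent);
    ``clusters`` (e.g. mother identifiers) activates the CR0 cluster
    sandwich; without clusters the robust covariance equals the model one.
    """
    X = _with_intercept(X)
    y = np.asarray(y, dtype=float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # noqa: BLE001 - statsmodels raises various types
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 30:
        raise SeparationError("diverging coefficients: data are (quasi-)separated")

    cov_model = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns,
                             columns=X.columns)
    n_clusters = None
    if clusters is not None:
        # CR0 sandwich: bread = model covariance (inverse information for the
        # canonical link), meat = outer products of cluster-summed scores.
        groups = pd.factorize(np.asarray(clusters))[0]
        n_clusters = int(groups.max()) + 1
        mu = np.asarray(res.fittedvalues)
        scores = X.to_numpy(dtype=float) * (y - mu)[:, None]
        cluster_scores = np.zeros((n_clusters, X.shape[1]))
        np.add.at(cluster_scores, groups, scores)
        meat = cluster_scores.T @ cluster_scores
        bread = cov_model.to_numpy()
        cov_robust = pd.DataFrame(bread @ meat @ bread, index=X.columns,
                                  columns=X.columns)
    else:
        cov_robust = cov_model
    return LogisticFit(params=pd.Series(params, index=X.columns),
                       cov_model=cov_model, cov_robust=cov_robust,
                       llf=float(res.llf), aic=float(res.aic),
                       nobs=int(res.nobs), converged=bool(res.converged),
                       n_clusters=n_clusters)


@dataclass
class EliminationStep:
    dropped: str
    p_value: float
    aic_before: float
    aic_after: float


@dataclass
class EliminationResult:
    fit: LogisticFit
    kept: list[str]
    forced: list[str]
    steps: list[EliminationStep] = field(default_factory=list)


def backward_eliminate(data: pd.DataFrame, outcome: str, candidates: list[str],
                       forced: list[str] = (), clusters: str | None = None,
                       alpha: float = 0.1) -> EliminationResult:
    """Backward elimination on robust Wald p-values.

    Starting from the saturated model (all candidates plus forced
    covariates), repeatedly drop the single candidate with the largest
    robust p >= alpha and refit; forced covariates are never dropped.
    Ties on p are broken toward the smaller absolute coefficient.
    """
    forced = list(forced)
    kept = list(candidates)
    groups = data[clusters] if clusters is not None else None
    steps: list[EliminationStep] = []
    while True:
        fit = fit_logistic(data[forced + kept], data[outcome], clusters=groups)
        if not kept:
            break
        p = fit.wald_p(robust=True)[kept]
        removable = p[p >= alpha]
        if removable.empty:
            break
        worst_p = removable.max()
        ties = removable.index[removable == worst_p]
        drop = min(ties, key=lambda name: abs(fit.params[name]))
        kept.remove(drop)
        refit = fit_logistic(data[forced + kept], data[outcome], clusters=groups)
        steps.append(EliminationStep(dropped=drop, p_value=float(worst_p),
                                     aic_before=fit.aic, aic_after=refit.aic))
        fit = refit
    return EliminationResult(fit=fit, kept=kept, forced=forced, steps=steps)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC: step-function TPF/FPF over descending score thresholds."""

    thresholds: np.ndarray
    tpf: np.ndarray
    fpf: np.ndarray
    auc: float


def auc_mann_whitney(scores, y) -> float:
    """AUC as the tie-corrected Mann-Whitney statistic (midranks)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC is undefined with a single-class outcome")
    ranks = rankdata(scores)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc(scores, y) -> RocCurve:
    """Empirical ROC curve over the unique score thresholds."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = np.asarray(y, dtype=bool)
    auc = auc_mann_whitney(scores, y)  # validates both classes present
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tps = np.cumsum(y[order])
    fps = np.cumsum(~y[order])
    last = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    thresholds = sorted_scores[last]
    tpf = tps[last] / tps[-1]
    fpf = fps[last] / fps[-1]
    return RocCurve(thresholds=thresholds, tpf=tpf, fpf=fpf, auc=auc)


def sensitivity_at_fpf(curve: RocCurve, fpf0: float = 0.10) -> float:
    """TPF of the ROC step function at a fixed FPF (largest FPF <= fpf0)."""
    idx = int(np.searchsorted(curve.fpf, fpf0, side="right")) - 1
    if idx < 0:
        return 0.0
    return float(curve.tpf[idx])


@dataclass(frozen=True)
class CentileRule:
    """Flag records whose predicted probability exceeds a stratum centile."""

    centile: float
    cutoff: float
    flags: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def centile_rule(probabilities, centile: float) -> CentileRule:
    """Nearest-rank percentile cutoff with strict '>' flagging.

    With all-equal probabilities nothing is flagged (the cutoff equals the
    common value); ties at the cutoff are never flagged.
    """
    if not 0 < centile < 100:
        raise ValueError("centile must lie strictly between 0 and 100")
    p = np.asarray(probabilities, dtype=float)
    ranked = np.sort(p)
    k = math.ceil(centile / 100 * len(p))
    cutoff = float(ranked[k - 1])
    return CentileRule(centile=centile, cutoff=cutoff, flags=p > cutoff)
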