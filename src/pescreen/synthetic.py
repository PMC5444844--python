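"""Synthetic birth-registry generator.

Emulates the statistical structure the screening analysis assumes: two
parity strata whose binary exposures are drawn at published registry
margins, and a preeclampsia outcome drawn from a logistic model whose
log-odds coefficients are the published mutually adjusted odds ratios.
The intercept of each stratum is calibrated by exact enumeration of the
2^k exposure cells so the expected incidence matches the published
parity-specific incidence (2.41 % multiparous, 5.57 % primiparous).

Exposures are independent Bernoulli by default (only margins are
published); an optional Gaussian-copula hook introduces pairwise
dependence.  Multiparous mothers contribute a truncated-geometric number
of pregnancies (1-4) under a shared ``mother_id``, giving the clustering
that motivates cluster-robust variance downstream.  Exposures are drawn
independently across a mother's pregnancies.

Random stream order per stratum (one ``numpy`` generator per run, strata
in listed order): exposure matrix, outcome draws, mother cluster sizes —
so a fixed seed fixes the output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from . import mbr_summary
from .registry import EXPOSURES, MULTIPAROUS, PRIMIPAROUS

MAX_ENUMERATED_EXPOSURES = 20


@dataclass(frozen=True)
class StratumConfig:
    """Generating model for one parity stratum.

    ``prevalence`` maps exposure name -> marginal Bernoulli probability;
    ``adjusted_or`` maps exposure name -> odds ratio whose log is the
    outcome-model coefficient; ``target_incidence`` is the marginal
    outcome probability the intercept is calibrated to.
    """

    parity: str
    n: int
    prevalence: Mapping[str, float]
    adjusted_or: Mapping[str, float]
    target_incidence: float
    exposure_corr: float | None = None  # optional Gaussian-copula pairwise rho

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("stratum size must be >= 1")
        if not 0 < self.target_incidence < 1:
            raise ValueError("target incidence must lie in (0, 1)")
        if set(self.prevalence) != set(self.adjusted_or):
            raise ValueError("prevalence and adjusted_or must cover the same exposures")
        for name, p in self.prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")

    @property
    def exposures(self) -> tuple[str, ...]:
        return tuple(e for e in EXPOSURES if e in self.prevalence)

    @property
    def beta(self) -> np.ndarray:
        return np.log([self.adjusted_or[e] for e in self.exposures])

    @property
    def prevalence_vector(self) -> np.ndarray:
        return np.array([self.prevalence[e] for e in self.exposures])


@dataclass(frozen=True)
class SyntheticConfig:
    """Whole-registry generating model (both strata plus clustering knobs)."""

    strata: tuple[StratumConfig, ...]
    pregnancies_per_mother_decay: float = 0.5   # geometric decay on {1..max}
    max_pregnancies_per_mother: int = 4
    emit_multiple_birth_duplicates: bool = False
    seed: int = 0


def default_config(n_per_stratum: int | Mapping[str, int] | None = None,
                   seed: int = 0, **kwargs) -> SyntheticConfig:
    """Registry-calibrated defaults: published margins, adjusted ORs and
    parity-specific incidences; full published stratum sizes unless
    ``n_per_stratum`` overrides them."""
    sizes = dict(mbr_summary.STRATUM_N)
    if isinstance(n_per_stratum, int):
        sizes = {s: n_per_stratum for s in sizes}
    elif n_per_stratum is not None:
        sizes.update(n_per_stratum)
    strata = tuple(
        StratumConfig(
            parity=stratum,
            n=sizes[stratum],
            prevalence=dict(mbr_summary.EXPOSURE_PREVALENCE[stratum]),
            adjusted_or=dict(mbr_summary.ADJUSTED_OR[stratum]),
            target_incidence=mbr_summary.PE_INCIDENCE[stratum],
        )
        for stratum in (MULTIPAROUS, PRIMIPAROUS)
    )
    return SyntheticConfig(strata=strata, seed=seed, **kwargs)


def _enumerate_cells(prevalence: np.ndarray, beta: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All 2^k exposure cells: (bit matrix, cell probability, X @ beta)."""
    k = len(prevalence)
    if k > MAX_ENUMERATED_EXPOSURES:
        raise ValueError(f"enumeration supports at most {MAX_ENUMERATED_EXPOSURES} exposures")
    bits = ((np.arange(2 ** k)[:, None] >> np.arange(k)[None, :]) & 1).astype(float)
    prob = np.prod(np.where(bits == 1, prevalence, 1 - prevalence), axis=1)
    lp = bits @ beta
    return bits, prob, lp


def calibrate_intercept(beta: Sequence[float], prevalence: Sequence[float],
                        target_incidence: float) -> float:
    """Intercept b0 with E[expit(b0 + X beta)] equal to the target incidence.

    Exposures are treated as independent Bernoulli; the expectation is an
    exact sum over the 2^k cells and is strictly increasing in b0, so the
    root is unique (solved by Brent's method to ~1e-12).
    """
    if not 0 < target_incidence < 1:
        raise ValueError("target incidence must lie strictly in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    prevalence = np.asarray(prevalence, dtype=float)
    if len(beta) == 0:
        return float(logit(target_incidence))
    _, prob, lp = _enumerate_cells(prevalence, beta)

    def achieved(b0: float) -> float:
        return float(prob @ expit(b0 + lp)) - target_incidence

    lo, hi = -60.0, 60.0
    return float(brentq(achieved, lo, hi, xtol=1e-13, rtol=8.9e-16))


def achieved_incidence(stratum: StratumConfig, b0: float | None = None) -> float:
    """Exact marginal outcome probability under the generating model."""
    beta, prev = stratum.beta, stratum.prevalence_vector
    if b0 is None:
        b0 = calibrate_intercept(beta, prev, stratum.target_incidence)
    _, prob, lp = _enumerate_cells(prev, beta)
    return float(prob @ expit(b0 + lp))


def _draw_exposures(stratum: StratumConfig, rng: np.random.Generator) -> np.ndarray:
    p = stratum.prevalence_vector
    n, k = stratum.n, len(p)
    if stratum.exposure_corr is None:
        return rng.random((n, k)) < p
    # Gaussian copula with exchangeable correlation rho
    rho = stratum.exposure_corr
    cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    return z < norm.ppf(p)


def _mother_sizes(n: int, decay: float, max_size: int, rng: np.random.Generator
                  ) -> np.ndarray:
    weights = decay ** np.arange(max_size)
    weights /= weights.sum()
    # draw generously, then trim to exactly n pregnancies
    draws = rng.choice(np.arange(1, max_size + 1), size=n, p=weights)
    total = np.cumsum(draws)
    stop = int(np.searchsorted(total, n))
    sizes = draws[: stop + 1].copy()
    sizes[-1] -= int(total[stop] - n)
    return sizes


def generate_stratum(stratum: StratumConfig, config: SyntheticConfig,
                     rng: np.random.Generator, id_prefix: str) -> pd.DataFrame:
    """One stratum of synthetic pregnancy records."""
    x = _draw_exposures(stratum, rng)
    b0 = calibrate_intercept(stratum.beta, stratum.prevalence_vector,
                             stratum.target_incidence)
    pe = rng.random(stratum.n) < expit(b0 + x @ stratum.beta)

    if stratum.parity == MULTIPAROUS:
        sizes = _mother_sizes(stratum.n, config.pregnancies_per_mother_decay,
                              config.max_pregnancies_per_mother, rng)
    else:
        sizes = np.ones(stratum.n, dtype=int)
    mother_idx = np.repeat(np.arange(len(sizes)), sizes)

    df = pd.DataFrame({
        "pregnancy_id": [f"{id_prefix}p{i:08d}" for i in range(stratum.n)],
        "mother_id": [f"{id_prefix}m{i:08d}" for i in mother_idx],
        "parity": stratum.parity,
        "pe": pe,
    })
    for j, name in enumerate(stratum.exposures):
        df[name] = x[:, j]
    for name in EXPOSURES:
        if name not in df.columns:
            df[name] = False
    df = df[["pregnancy_id", "mother_id", "parity", "pe", *EXPOSURES]]

    if config.emit_multiple_birth_duplicates:
        twins = df[df["multiple_pregnancy"]]
        df = pd.concat([df, twins], ignore_index=True)
        df = df.sort_values("pregnancy_id", kind="stable").reset_index(drop=True)
    return df


def generate(config: SyntheticConfig) -> pd.DataFrame:
    """Full synthetic registry, deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    parts = [
        generate_stratum(stratum, config, rng, id_prefix=stratum.parity[:1])
        for stratum in config.strata
    ]
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class PopulationDA:
    """Closed-form population accuracy of a marker under the generating model
    (percentages in percent, mirroring the empirical summary)."""

    ar: float
    ar_unexposed: float
    af: float
    tpf: float
    fpf: float
    lr_pos: float
    lr_neg: float
    or_: float


def expected_da(stratum: StratumConfig,
                marker: str | Callable[[Mapping[str, bool]], bool]) -> PopulationDA:
    """Exact population discriminatory accuracy of a marker.

    ``marker`` is an exposure name, the string ``"pe"`` (the outcome
    itself), or a boolean function of the exposure-flag mapping; values are
    obtained by enumerating the exposure cells, so simulation estimates
    converge to them as n grows.  Dependence-structured configurations are
    not supported.
    """
    if stratum.exposure_corr is not None:
        raise ValueError("expected_da supports independent-exposure configs only")
    names = stratum.exposures
    bits, prob, lp = _enumerate_cells(stratum.prevalence_vector, stratum.beta)
    b0 = calibrate_intercept(stratum.beta, stratum.prevalence_vector,
                             stratum.target_incidence)
    pi = expit(b0 + lp)

    if marker == "pe":
        return PopulationDA(ar=100.0, ar_unexposed=0.0, af=100.0, tpf=100.0,
                            fpf=0.0, lr_pos=np.inf, lr_neg=0.0, or_=np.inf)
    if callable(marker):
        m = np.array([bool(marker(dict(zip(names, row.astype(bool)))))
                      for row in bits])
    else:
        if marker not in names:
            raise KeyError(f"unknown exposure {marker!r}")
        m = bits[:, names.index(marker)].astype(bool)

    p_case = float(prob @ pi)
    tp = float(prob[m] @ pi[m])
    fp = float(prob[m] @ (1 - pi[m]))
    fn = p_case - tp
    tn = float(prob[~m] @ (1 - pi[~m]))

    tpf = tp / p_case
    fpf = fp / (1 - p_case)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr_pos = np.inf if fpf == 0 else tpf / fpf
        lr_neg = (1 - tpf) / (1 - fpf) if fpf < 1 else np.inf
        or_ = np.inf if fp * fn == 0 else (tp * tn) / (fp * fn)
    ar = tp / (tp + fp) if tp + fp > 0 else np.nan
    ar_un = fn / (fn + tn)
    return PopulationDA(ar=100 * ar, ar_unexposed=100 * ar_un, af=100 * (ar - ar_un),
                        tpf=100 * tpf, fpf=100 * fpf,
                        lr_pos=float(lr_pos), lr_neg=float(lr_neg), or_=float(or_))


# -- YAML config round-trip -------------------------------------------------

def dump_config(config: SyntheticConfig, path) -> None:
    payload = dataclasses.asdict(config)
    payload["strata"] = [dataclasses.asdict(s) for s in config.strata]
    for s in payload["strata"]:
        s["prevalence"] = {k: float(v) for k, v in s["prevalence"].items()}
        s["adjusted_or"] = {k: float(v) for k, v in s["adjusted_or"].items()}
        s["target_incidence"] = float(s["target_incidence"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    strata = tuple(StratumConfig(**s) for s in payload.pop("strata"))
    return SyntheticConfig(strata=strata, **payload)


def packaged_default_config_path() -> "Path":
    """Path of the shipped registry-calibrated YAML config."""
    from pathlib import Path

    return Path(__file__).parent / "data" / "mbr_defaults.yaml"
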