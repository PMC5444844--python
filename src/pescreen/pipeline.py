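"""End-to-end screening-rule evaluation over a pregnancy registry.

Stage flow (mirroring how such registry analyses proceed): load or
simulate the registry -> deduplicate multiple births -> screen every
factor for interaction with parity on both scales -> stratify by parity
-> per stratum: single-factor accuracy, recreated guideline rules,
forest-guided combination subgroups, and the multiple logistic model with
predicted-probability centile rules.  Each stage writes a tidy CSV into
the output directory and appends to a JSON manifest (seeds, record-count
deltas, eliminated variables, cutoffs), so a run is auditable and, for a
fixed config and seed, byte-identical.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import build_contingency, da_summary, rule_in_out_flags
from .forest import ForestConfig, fit_forest
from .glm import backward_eliminate, centile_rule, roc, sensitivity_at_fpf
from .interaction import interaction_screen
from .registry import (EXPOSURES, MULTIPAROUS, PRIMIPAROUS, RISK_FACTORS,
                       read_registry, select_one_per_pregnancy, validate)
from .rules import GUIDELINE_RULES, SOCIAL_COVARIATES, classify, subgroup_da
from .synthetic import SyntheticConfig, default_config, generate
from .registry import select_one_per_mother

DEFAULT_CENTILES = (95, 97, 99)


@dataclass
class AnalysisConfig:
    """What to analyse and where to write it."""

    out_dir: Path
    registry_path: Path | None = None
    synthetic: SyntheticConfig | None = None
    seed: int = 0
    subgroup_k: int = 4
    centiles: tuple[int, ...] = DEFAULT_CENTILES
    forest: ForestConfig = field(default_factory=lambda: ForestConfig(n_trees=200))

    def __post_init__(self) -> None:
        if (self.registry_path is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of registry_path or synthetic config")


def _da_row(marker, outcome, label: str) -> dict:
    da = da_summary(build_contingency(marker, outcome))
    return {
        "marker": label,
        "n": int(np.asarray(marker, dtype=bool).sum()),
        "ar": da.ar.value, "af": da.af.value,
        "tpf": da.tpf.value, "tpf_lo": da.tpf.lo, "tpf_hi": da.tpf.hi,
        "fpf": da.fpf.value, "fpf_lo": da.fpf.lo, "fpf_hi": da.fpf.hi,
        "lr_pos": da.lr_pos.value, "lr_pos_lo": da.lr_pos.lo, "lr_pos_hi": da.lr_pos.hi,
        "lr_neg": da.lr_neg.value, "lr_neg_lo": da.lr_neg.lo, "lr_neg_hi": da.lr_neg.hi,
        "or_crude": da.or_crude.value, "or_crude_lo": da.or_crude.lo,
        "or_crude_hi": da.or_crude.hi,
        "lr_class": "/".join(sorted(rule_in_out_flags(da))),
    }


def _stratum_factors(stratum: str) -> list[str]:
    factors = [f for f in EXPOSURES]
    if stratum == PRIMIPAROUS:
        factors.remove("previous_pe")
    return factors


def _clinical_factors(stratum: str) -> list[str]:
    factors = [f for f in RISK_FACTORS]
    if stratum == PRIMIPAROUS:
        factors.remove("previous_pe")
    return factors


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pescreen_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": [],
    }

    def log(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})

    # -- input ---------------------------------------------------------
    if config.registry_path is not None:
        records = read_registry(config.registry_path)
        log("load", path=str(config.registry_path), n_records=len(records))
    else:
        records = generate(config.synthetic)
        log("simulate", n_records=len(records), seed=config.synthetic.seed)

    n_before = len(records)
    records = select_one_per_pregnancy(records, seed=config.seed)
    records = validate(records)
    log("dedup_multiple_births", n_before=n_before, n_after=len(records))

    # -- interaction screen --------------------------------------------
    records = records.assign(primiparous=(records["parity"] == PRIMIPAROUS))
    screen_factors = tuple(f for f in EXPOSURES if f != "previous_pe")
    screen = interaction_screen(records, screen_factors, stratifier="primiparous",
                                clusters="mother_id")
    screen.to_csv(out / "interaction_screen.csv", index=False)
    significant = screen[(screen["multiplicative"] != "nonsignificant")
                         | (screen["additive"] != "nonsignificant")]
    stratify = len(significant) > 0
    log("interaction_screen", n_factors=len(screen),
        n_significant=len(significant), stratified=stratify)

    strata = (MULTIPAROUS, PRIMIPAROUS) if stratify else (None,)
    for stratum in strata:
        sub = records if stratum is None else records[records["parity"] == stratum]
        tag = stratum or "overall"
        y = sub["pe"].to_numpy()

        # single-factor DA plus mutually adjusted ORs
        factors = _stratum_factors(tag) if stratum else list(EXPOSURES)
        rows = [_da_row(sub[f].to_numpy(), y, f) for f in factors]
        single = pd.DataFrame(rows)
        adj = backward_eliminate(sub, "pe", candidates=[], forced=factors,
                                 clusters="mother_id")
        ors = adj.fit.odds_ratios(robust=True)
        single["or_adj"] = [ors.loc[f, "or"] for f in factors]
        single["or_adj_lo"] = [ors.loc[f, "lo"] for f in factors]
        single["or_adj_hi"] = [ors.loc[f, "hi"] for f in factors]
        single.to_csv(out / f"single_factor_da_{tag}.csv", index=False)
        log("single_factor_da", stratum=tag, n=len(sub), n_pe=int(y.sum()))

        # recreated guideline rules
        grows = []
        for rule in GUIDELINE_RULES:
            flag = classify(rule, sub)
            row = _da_row(flag.to_numpy(), y, rule.name)
            X = pd.DataFrame({rule.name: flag.astype(float)})
            for cov in SOCIAL_COVARIATES:
                X[cov] = sub[cov].astype(float)
            fit = backward_eliminate(pd.concat([X, sub[["pe", "mother_id"]]], axis=1),
                                     "pe", candidates=[],
                                     forced=[rule.name, *SOCIAL_COVARIATES],
                                     clusters="mother_id").fit
            ot = fit.odds_ratios(robust=True)
            row["or_adj"] = ot.loc[rule.name, "or"]
            row["or_adj_lo"] = ot.loc[rule.name, "lo"]
            row["or_adj_hi"] = ot.loc[rule.name, "hi"]
            grows.append(row)
        pd.DataFrame(grows).to_csv(out / f"guideline_da_{tag}.csv", index=False)
        log("guideline_da", stratum=tag)

        # forest-guided subgroups
        one_per_mother = select_one_per_mother(sub, seed=config.seed + 1)
        feats = _clinical_factors(tag) if stratum else list(RISK_FACTORS)
        forest_X = one_per_mother[feats + list(SOCIAL_COVARIATES)]
        ranking = fit_forest(forest_X, one_per_mother["pe"],
                             ForestConfig(**{**config.forest.__dict__,
                                             "seed": config.seed + 2}))
        ranking.table.to_csv(out / f"forest_importance_{tag}.csv", index=False)
        clinical_ranked = [v for v in ranking.table["variable"] if v in feats]
        top = clinical_ranked[: config.subgroup_k]
        sg = subgroup_da(sub, tuple(top)) if stratum else None
        if sg is not None:
            sg.rows.to_csv(out / f"subgroup_da_{tag}.csv", index=False)
        log("forest_subgroups", stratum=tag, top_variables=top,
            n_one_per_mother=len(one_per_mother))

        # multiple model, ROC, centile rules
        candidates = _clinical_factors(tag) if stratum else list(RISK_FACTORS)
        elim = backward_eliminate(sub, "pe", candidates=candidates,
                                  forced=list(SOCIAL_COVARIATES),
                                  clusters="mother_id", alpha=0.1)
        coef = elim.fit.odds_ratios(robust=True)
        coef.insert(0, "term", coef.index)
        coef.to_csv(out / f"model_coefficients_{tag}.csv", index=False)
        probs = elim.fit.predict(sub[elim.forced + elim.kept])
        curve = roc(probs, y)
        crow = []
        for c in config.centiles:
            rule = centile_rule(probs, c)
            row = _da_row(rule.flags, y, f"centile_{c}")
            row["cutoff"] = rule.cutoff
            crow.append(row)
        centiles = pd.DataFrame(crow)
        centiles["auc"] = curve.auc
        centiles["tpf_at_fpf10"] = sensitivity_at_fpf(curve, 0.10)
        centiles["aic"] = elim.fit.aic
        centiles.to_csv(out / f"centile_da_{tag}.csv", index=False)
        log("centile_model", stratum=tag,
            eliminated=[s.dropped for s in elim.steps], kept=elim.kept,
            auc=curve.auc, tpf_at_fpf10=sensitivity_at_fpf(curve, 0.10),
            aic=elim.fit.aic,
            cutoffs={str(c): float(centile_rule(probs, c).cutoff)
                     for c in config.centiles})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def simulate_registry(out_path: Path, n_per_stratum: int | None = None,
                      seed: int = 0, config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic registry CSV (default registry-calibrated config)."""
    from .registry import write_registry

    cfg = config if config is not None else default_config(n_per_stratum, seed=seed)
    records = generate(cfg)
    write_registry(records, out_path)
    return records
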