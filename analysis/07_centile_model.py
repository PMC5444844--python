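"""Multiple logistic model and predicted-probability centile rules.

Per stratum: backward elimination (robust Wald p >= 0.1) from the
saturated clinical model with the social covariates forced, then AUC,
sensitivity at 10 % FPF, and the accuracy of flagging pregnancies above
the 95th/97th/99th centile of predicted probability.
"""

import pandas as pd

from common import RESULTS, load_registry
from pescreen.accuracy import build_contingency, da_summary, rule_in_out_flags
from pescreen.glm import backward_eliminate, centile_rule, roc, sensitivity_at_fpf
from pescreen.registry import PRIMIPAROUS, RISK_FACTORS
from pescreen.rules import SOCIAL_COVARIATES


def main() -> None:
    records = load_registry()
    for stratum, sub in records.groupby("parity"):
        candidates = [f for f in RISK_FACTORS
                      if not (stratum == PRIMIPAROUS and f == "previous_pe")]
        elim = backward_eliminate(sub, "pe", candidates=candidates,
                                  forced=list(SOCIAL_COVARIATES),
                                  clusters="mother_id", alpha=0.1)
        coef = elim.fit.odds_ratios(robust=True)
        coef.insert(0, "term", coef.index)
        coef.to_csv(RESULTS / f"model_coefficients_{stratum}.csv", index=False)

        probs = elim.fit.predict(sub[elim.forced + elim.kept])
        curve = roc(probs, sub["pe"])
        dropped = [s.dropped for s in elim.steps]
        print(f"{stratum}: eliminated {dropped or 'nothing'}; "
              f"AUC = {100 * curve.auc:.2f}, "
              f"TPF at 10 % FPF = {100 * sensitivity_at_fpf(curve, 0.10):.2f} %, "
              f"AIC = {elim.fit.aic:.0f}")

        rows = []
        for c in (95, 97, 99):
            rule = centile_rule(probs, c)
            da = da_summary(build_contingency(rule.flags, sub["pe"]))
            rows.append({
                "centile": c, "cutoff": rule.cutoff, "n": rule.n_flagged,
                "ar": da.ar.value, "af": da.af.value, "tpf": da.tpf.value,
                "fpf": da.fpf.value, "lr_pos": da.lr_pos.value,
                "lr_neg": da.lr_neg.value,
                "lr_class": "/".join(sorted(rule_in_out_flags(da))),
            })
            print(f"  >{c} centile (cutoff {rule.cutoff:.2f}): n={rule.n_flagged}, "
                  f"AR={da.ar.value:.1f} %, LR+={da.lr_pos.value:.2f}")
        table = pd.DataFrame(rows)
        table["auc"] = curve.auc
        table["tpf_at_fpf10"] = sensitivity_at_fpf(curve, 0.10)
        table["aic"] = elim.fit.aic
        table.to_csv(RESULTS / f"centile_da_{stratum}.csv", index=False)


if __name__ == "__main__":
    main()
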