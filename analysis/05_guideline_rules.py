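"""Accuracy of three recreated guideline definitions of high risk.

Rules: any listed risk factor; one major or two moderate factors
(NICE-style); one major factor counting multiple pregnancy as major
(WHO-style).  Evaluated per parity stratum with adjusted ORs against the
social covariates.
"""

import pandas as pd

from common import RESULTS, load_registry
from pescreen.accuracy import build_contingency, da_summary, rule_in_out_flags
from pescreen.glm import fit_logistic
from pescreen.rules import GUIDELINE_RULES, SOCIAL_COVARIATES, classify


def main() -> None:
    records = load_registry()
    for stratum, sub in records.groupby("parity"):
        rows = []
        for rule in GUIDELINE_RULES:
            flag = classify(rule, sub)
            da = da_summary(build_contingency(flag, sub["pe"]))
            X = pd.DataFrame({rule.name: flag.astype(float)})
            for cov in SOCIAL_COVARIATES:
                X[cov] = sub[cov].astype(float)
            fit = fit_logistic(X, sub["pe"], clusters=sub["mother_id"])
            ors = fit.odds_ratios(robust=True)
            rows.append({
                "rule": rule.name, "n": int(flag.sum()),
                "ar": da.ar.value, "af": da.af.value, "tpf": da.tpf.value,
                "fpf": da.fpf.value, "lr_pos": da.lr_pos.value,
                "lr_neg": da.lr_neg.value,
                "or_adj": ors.loc[rule.name, "or"],
                "lr_class": "/".join(sorted(rule_in_out_flags(da))),
            })
        table = pd.DataFrame(rows)
        table.to_csv(RESULTS / f"guideline_da_{stratum}.csv", index=False)
        print(f"{stratum}:")
        for _, r in table.iterrows():
            print(f"  {r['rule']}: n={r['n']}, TPF={r['tpf']:.1f} %, "
                  f"FPF={r['fpf']:.1f} %, LR+={r['lr_pos']:.2f}, LR-={r['lr_neg']:.2f}")


if __name__ == "__main__":
    main()
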