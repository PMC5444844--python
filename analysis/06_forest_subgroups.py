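"""Forest-guided variable selection and exact-combination subgroups.

A random forest (one record per mother, to respect independence) ranks
the clinical factors per stratum; the top four define the exact-match
combination subgroups whose discriminatory accuracy is then tabulated
against the whole stratum.
"""

from common import RESULTS, SEED, load_registry
from pescreen.forest import ForestConfig, fit_forest
from pescreen.registry import PRIMIPAROUS, RISK_FACTORS, select_one_per_mother
from pescreen.rules import SOCIAL_COVARIATES, subgroup_da


def main() -> None:
    records = load_registry()
    for stratum, sub in records.groupby("parity"):
        feats = [f for f in RISK_FACTORS
                 if not (stratum == PRIMIPAROUS and f == "previous_pe")]
        independent = select_one_per_mother(sub, seed=SEED + 1)
        ranking = fit_forest(independent[feats + list(SOCIAL_COVARIATES)],
                             independent["pe"],
                             ForestConfig(n_trees=200, seed=SEED + 2))
        ranking.table.to_csv(RESULTS / f"forest_importance_{stratum}.csv", index=False)
        top = [v for v in ranking.table["variable"] if v in feats][:4]
        print(f"{stratum}: forest top-4 clinical factors = {', '.join(top)}")

        table = subgroup_da(sub, tuple(top))
        table.rows.to_csv(RESULTS / f"subgroup_da_{stratum}.csv", index=False)
        populated = table.rows[table.rows["n"] > 0]
        stable = populated[populated["n"] >= 20]  # cells below this are noise
        best = stable.loc[stable["lr_pos"].idxmax()]
        print(f"  best combination with n >= 20 over ({', '.join(top)}): "
              f"{best['combination']}, n={best['n']}, AR={best['ar']:.1f} %, "
              f"LR+={best['lr_pos']:.1f}")
        rule_in = populated[populated["lr_pos"] > 10]
        print(f"  {len(rule_in)} of {len(populated)} populated combinations rule in "
              "(LR+ > 10)")


if __name__ == "__main__":
    main()
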