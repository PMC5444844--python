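"""Generator calibration, determinism and its closed-form accuracy oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from pescreen import mbr_summary as mbr
from pescreen.accuracy import build_contingency, da_summary
from pescreen.registry import validate
from pescreen.synthetic import (StratumConfig, SyntheticConfig, achieved_incidence,
                                calibrate_intercept, default_config, dump_config,
                                expected_da, generate, load_config)


def _stratum(prev, ors, target, **kw):
    names = [f"x{i}" for i in range(len(prev))]
    # reuse real exposure names so StratumConfig ordering applies
    from pescreen.registry import EXPOSURES
    names = list(EXPOSURES[: len(prev)])
    return StratumConfig(parity="multiparous", n=kw.pop("n", 1000),
                         prevalence=dict(zip(names, prev)),
                         adjusted_or=dict(zip(names, ors)),
                         target_incidence=target, **kw)


class TestCalibrateIntercept:
    def test_no_exposures_closed_form(self):
        assert calibrate_intercept([], [], 0.0241) == pytest.approx(logit(0.0241))

    def test_two_cell_enumeration_matches_monte_carlo(self):
        b0 = calibrate_intercept([1.0], [0.5], 0.05)
        exact = 0.5 * expit(b0) + 0.5 * expit(b0 + 1.0)
        assert exact == pytest.approx(0.05, abs=1e-10)
        rng = np.random.default_rng(1)
        n = 1_000_000
        x = rng.random(n) < 0.5
        y = rng.random(n) < expit(b0 + x)
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(y.mean() - 0.05) < 3 * se

    def test_incidence_monotone_in_beta(self):
        prev = [0.3, 0.1]
        b0 = calibrate_intercept([0.5, 1.0], prev, 0.03)
        s = _stratum(prev, [np.e ** 0.5, np.e], 0.03)
        base = achieved_incidence(s, b0)
        bumped = achieved_incidence(_stratum(prev, [np.e ** 1.5, np.e], 0.03), b0)
        assert bumped > base

    def test_default_strata_hit_published_incidences(self):
        for stratum in default_config().strata:
            assert abs(achieved_incidence(stratum) - stratum.target_incidence) < 1e-10

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_intercept([0.1], [0.5], 1.0)


class TestGenerate:
    def test_seed_fixes_output_exactly(self, tmp_path):
        cfg = default_config(n_per_stratum=2000, seed=5)
        a, b = generate(cfg), generate(cfg)
        pd.testing.assert_frame_equal(a, b)
        from pescreen.registry import write_registry
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_registry(a, pa)
        write_registry(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_incidence_and_margins_near_configured(self, small_registry):
        cfg = default_config()
        for stratum in cfg.strata:
            sub = small_registry[small_registry["parity"] == stratum.parity]
            n = len(sub)
            p = stratum.target_incidence
            assert abs(sub["pe"].mean() - p) < 3 * math.sqrt(p * (1 - p) / n)
            for name in stratum.exposures:
                q = stratum.prevalence[name]
                assert abs(sub[name].mean() - q) < 4 * math.sqrt(q * (1 - q) / n)

    def test_null_model_gives_unit_odds_ratios(self):
        prev = [0.3, 0.1, 0.2]
        s = _stratum(prev, [1.0, 1.0, 1.0], 0.05, n=60_000)
        df = generate(SyntheticConfig(strata=(s,), seed=8))
        for name in s.exposures:
            da = da_summary(build_contingency(df[name], df["pe"]))
            assert da.or_crude.lo < 1 < da.or_crude.hi

    def test_records_pass_validation_and_cluster_structure(self, small_registry):
        out = validate(small_registry)
        multi = out[out["parity"] == "multiparous"]
        sizes = multi.groupby("mother_id").size()
        assert sizes.max() <= 4 and (sizes > 1).any()
        primi = out[out["parity"] == "primiparous"]
        assert primi.groupby("mother_id").size().max() == 1
        assert not primi["previous_pe"].any()

    def test_multiple_birth_duplicates_share_pregnancy_id(self):
        cfg = default_config(n_per_stratum=3000, seed=2,
                             emit_multiple_birth_duplicates=True)
        df = generate(cfg)
        dup = df[df["pregnancy_id"].duplicated(keep=False)]
        assert len(dup) > 0
        assert dup["multiple_pregnancy"].all()
        from pescreen.registry import select_one_per_pregnancy
        dedup = select_one_per_pregnancy(df, seed=0)
        assert dedup["pregnancy_id"].is_unique


class TestExpectedDa:
    def test_outcome_as_marker_is_perfect(self):
        s = _stratum([0.2], [2.0], 0.05)
        da = expected_da(s, "pe")
        assert da.tpf == 100 and da.fpf == 0 and math.isinf(da.lr_pos)

    def test_null_exposure_has_unit_lr(self):
        s = _stratum([0.3], [1.0], 0.05)
        da = expected_da(s, list(s.exposures)[0])
        assert da.lr_pos == pytest.approx(1.0, abs=1e-12)
        assert da.af == pytest.approx(0.0, abs=1e-9)

    def test_three_exposure_config_matches_brute_force(self):
        prev = [0.25, 0.1, 0.05]
        ors = [2.0, 3.0, 1.5]
        s = _stratum(prev, ors, 0.04)
        name = list(s.exposures)[1]
        da = expected_da(s, name)
        # brute force over the 8 cells
        from itertools import product
        b0 = calibrate_intercept(np.log(ors), prev, 0.04)
        tp = fp = fn = tn = 0.0
        for bits in product((0, 1), repeat=3):
            pr = np.prod([p if b else 1 - p for p, b in zip(prev, bits)])
            pi = expit(b0 + sum(b * math.log(o) for b, o in zip(bits, ors)))
            if bits[1]:
                tp += pr * pi
                fp += pr * (1 - pi)
            else:
                fn += pr * pi
                tn += pr * (1 - pi)
        assert da.tpf == pytest.approx(100 * tp / (tp + fn), rel=1e-12)
        assert da.fpf == pytest.approx(100 * fp / (fp + tn), rel=1e-12)
        assert da.lr_pos == pytest.approx((tp / (tp + fn)) / (fp / (fp + tn)), rel=1e-12)

    def test_simulation_converges_to_expected(self):
        prev = [0.2, 0.1, 0.3, 0.05, 0.15]
        ors = [3.0, 1.5, 0.8, 5.0, 1.0]
        s = _stratum(prev, ors, 0.05, n=1_000_000)
        df = generate(SyntheticConfig(strata=(s,), seed=77))
        name = list(s.exposures)[0]
        pop = expected_da(s, name)
        emp = da_summary(build_contingency(df[name], df["pe"]))
        assert emp.tpf.value == pytest.approx(pop.tpf, rel=0.02)
        assert emp.fpf.value == pytest.approx(pop.fpf, rel=0.02)
        assert emp.lr_pos.value == pytest.approx(pop.lr_pos, rel=0.03)

    def test_dependency_config_unsupported(self):
        s = _stratum([0.2, 0.1], [2.0, 1.5], 0.05, exposure_corr=0.3)
        with pytest.raises(ValueError, match="independent"):
            expected_da(s, list(s.exposures)[0])


def test_copula_dependence_induces_positive_association():
    s = _stratum([0.3, 0.3], [1.0, 1.0], 0.05, n=40_000, exposure_corr=0.5)
    df = generate(SyntheticConfig(strata=(s,), seed=4))
    a, b = list(s.exposures)[:2]
    phi = np.corrcoef(df[a], df[b])[0, 1]
    assert phi > 0.2


def test_packaged_config_matches_published_defaults():
    from pescreen.synthetic import load_config, packaged_default_config_path
    shipped = load_config(packaged_default_config_path())
    fresh = default_config(seed=0)
    assert shipped == fresh
    assert shipped.strata[0].n == mbr.STRATUM_N["multiparous"]


def test_yaml_config_round_trip(tmp_path):
    cfg = default_config(n_per_stratum=500, seed=9)
    path = tmp_path / "cfg.yaml"
    dump_config(cfg, path)
    back = load_config(path)
    assert back == cfg
    pd.testing.assert_frame_equal(generate(back), generate(cfg))
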