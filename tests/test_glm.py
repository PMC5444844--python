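"""Logistic engine: fits, robust variance, elimination, ROC, centiles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from pescreen import glm
from pescreen import mbr_summary as mbr


def _expand_2x2(ct):
    """Record-level frame from a contingency table."""
    x = np.r_[np.ones(ct.tp + ct.fp), np.zeros(ct.fn + ct.tn)]
    y = np.r_[np.ones(ct.tp), np.zeros(ct.fp), np.ones(ct.fn), np.zeros(ct.tn)]
    return pd.DataFrame({"x": x, "y": y})


class TestFitLogistic:
    def test_single_predictor_reproduces_crude_or(self):
        # reconstructed chronic-hypertension table, multiparous stratum
        ct = mbr.reconstruct_contingency(2851, 20.1, stratum="multiparous")
        df = _expand_2x2(ct)
        fit = glm.fit_logistic(df[["x"]], df["y"])
        or_hat = math.exp(fit.params["x"])
        assert or_hat == pytest.approx((ct.tp * ct.tn) / (ct.fp * ct.fn), rel=1e-6)
        assert or_hat == pytest.approx(10.8, rel=0.02)

    def test_independent_outcome_gives_null_slopes(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.random(20_000) < 0.3,
                           "b": rng.random(20_000) < 0.5}).astype(float)
        y = rng.random(20_000) < 0.2
        fit = glm.fit_logistic(df, y)
        assert abs(fit.params["a"]) < 3 * fit.se()["a"]
        assert abs(fit.params["b"]) < 3 * fit.se()["b"]
        assert fit.params["const"] == pytest.approx(math.log(y.mean() / (1 - y.mean())),
                                                    abs=0.1)

    def test_toy_fit_matches_grid_search(self):
        # 6-row toy: brute-force likelihood grid maximization over (b0, b1),
        # refined iteratively and independently of the IRLS path
        x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        yy = np.array([0, 0, 1, 0, 1, 1], dtype=float)

        def nll(b0, b1):
            lp = b0[..., None] + b1[..., None] * x
            p = 1 / (1 + np.exp(-lp))
            return -np.sum(yy * np.log(p) + (1 - yy) * np.log(1 - p), axis=-1)

        center, width = np.zeros(2), 5.0
        for _ in range(7):
            g0 = center[0] + np.linspace(-width, width, 41)
            g1 = center[1] + np.linspace(-width, width, 41)
            bb0, bb1 = np.meshgrid(g0, g1, indexing="ij")
            vals = nll(bb0.ravel(), bb1.ravel())
            k = int(np.argmin(vals))
            center = np.array([bb0.ravel()[k], bb1.ravel()[k]])
            width /= 10

        fit = glm.fit_logistic(pd.DataFrame({"x": x}), yy)
        assert fit.params["const"] == pytest.approx(center[0], abs=1e-4)
        assert fit.params["x"] == pytest.approx(center[1], abs=1e-4)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings(
        "ignore::statsmodels.tools.sm_exceptions.PerfectSeparationWarning")
    def test_separation_raises(self):
        df = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1], "y": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(glm.SeparationError):
            glm.fit_logistic(df[["x"]], df["y"])

    def test_aic_definition(self):
        df = pd.DataFrame({"x": [0, 0, 1, 1, 0, 1], "y": [0, 1, 0, 1, 1, 0]})
        fit = glm.fit_logistic(df[["x"]], df["y"])
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.llf)


class TestRobustVariance:
    def test_singleton_clusters_equal_hc0_sandwich(self):
        # CR0 with one record per cluster is exactly the HC0 sandwich
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.random(500) < 0.4}).astype(float)
        y = (rng.random(500) < 0.3).astype(float)
        fit = glm.fit_logistic(df, y, clusters=np.arange(500))
        ref = sm.GLM(y, sm.add_constant(df), family=sm.families.Binomial()).fit(
            cov_type="HC0")
        np.testing.assert_allclose(fit.cov_robust.to_numpy(),
                                   np.asarray(ref.cov_params()), rtol=1e-6)

    def test_matches_statsmodels_cluster_cov(self, multiparous):
        import statsmodels.api as sm
        sub = multiparous.head(8000)
        feats = ["hbp", "obesity", "previous_pe"]
        fit = glm.fit_logistic(sub[feats], sub["pe"], clusters=sub["mother_id"])
        groups = pd.factorize(sub["mother_id"])[0]
        ref = sm.GLM(sub["pe"].astype(float),
                     sm.add_constant(sub[feats].astype(float)),
                     family=sm.families.Binomial()).fit(
            cov_type="cluster", cov_kwds={"groups": groups, "use_correction": False})
        np.testing.assert_allclose(fit.cov_robust.to_numpy(),
                                   np.asarray(ref.cov_params()), rtol=1e-5)

    def test_robust_se_close_to_model_se_under_correct_model(self, multiparous):
        feats = ["hbp", "obesity", "previous_pe", "multiple_pregnancy"]
        fit = glm.fit_logistic(multiparous[feats], multiparous["pe"],
                               clusters=multiparous["mother_id"])
        ratio = fit.se(robust=True) / fit.se(robust=False)
        # outcomes are independent given X here, so clustering changes little
        assert ((ratio - 1).abs() < 0.15).all()


class TestBackwardElimination:
    def test_pure_noise_candidate_dropped(self, multiparous):
        rng = np.random.default_rng(12)
        data = multiparous.head(30_000).copy()
        data["noise"] = (rng.random(len(data)) < 0.3).astype(float)
        res = glm.backward_eliminate(
            data, "pe", candidates=["hbp", "previous_pe", "obesity", "noise"],
            forced=["smoker"], clusters="mother_id")
        assert "noise" not in res.kept
        assert {"hbp", "previous_pe", "obesity"} <= set(res.kept)
        assert "smoker" in res.fit.names

    def test_zero_candidates_returns_forced_model(self, multiparous):
        res = glm.backward_eliminate(multiparous.head(2000), "pe",
                                     candidates=[], forced=["obesity"])
        assert res.kept == [] and res.steps == []
        assert set(res.fit.names) == {"const", "obesity"}

    def test_strong_effects_all_retained(self):
        rng = np.random.default_rng(5)
        n = 100_000
        x = pd.DataFrame({f"v{i}": (rng.random(n) < 0.2).astype(float)
                          for i in range(4)})
        lp = -3 + x.to_numpy() @ np.full(4, math.log(2.0))
        y = rng.random(n) < 1 / (1 + np.exp(-lp))
        data = x.assign(pe=y.astype(float))
        res = glm.backward_eliminate(data, "pe",
                                     candidates=list(x.columns), forced=[])
        assert res.kept == list(x.columns)


class TestRoc:
    @given(st.lists(st.tuples(st.integers(0, 5), st.booleans()),
                    min_size=4, max_size=20))
    @settings(max_examples=150, deadline=None)
    def test_auc_equals_pairwise_concordance(self, pairs):
        scores = np.array([s for s, _ in pairs], dtype=float)
        y = np.array([o for _, o in pairs])
        if y.all() or not y.any():
            return
        auc = glm.auc_mann_whitney(scores, y)
        pos = scores[y]
        neg = scores[~y]
        conc = sum(1.0 if p > q else 0.5 if p == q else 0.0
                   for p, q in itertools.product(pos, neg))
        assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_perfect_separation_auc_one(self):
        assert glm.roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]).auc == 1.0

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(2)
        y = rng.random(20_000) < 0.5
        auc = glm.auc_mann_whitney(rng.random(20_000), y)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.random(500)
        y = rng.random(500) < scores
        a1 = glm.auc_mann_whitney(scores, y)
        a2 = glm.auc_mann_whitney(np.log(scores / (1 - scores)), y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            glm.auc_mann_whitney([0.1, 0.2], [1, 1])

    def test_roc_monotone_and_sensitivity_lookup(self):
        rng = np.random.default_rng(9)
        scores = rng.random(2000)
        y = rng.random(2000) < scores
        curve = glm.roc(scores, y)
        assert (np.diff(curve.tpf) >= 0).all() and (np.diff(curve.fpf) >= 0).all()
        s = glm.sensitivity_at_fpf(curve, 0.10)
        idx = np.searchsorted(curve.fpf, 0.10, side="right") - 1
        assert s == curve.tpf[idx]
        assert 0 <= s <= 1


class TestCentileRule:
    def test_nearest_rank_on_uniform_grid(self):
        probs = np.arange(1, 101) / 100
        rule = glm.centile_rule(probs, 95)
        assert rule.n_flagged == 5
        assert rule.cutoff == 0.95

    def test_all_equal_probabilities_flag_nothing(self):
        rule = glm.centile_rule(np.full(50, 0.3), 97)
        assert rule.n_flagged == 0

    def test_flag_fraction_near_complement(self):
        rng = np.random.default_rng(21)
        probs = rng.random(10_000)
        for c in (95, 97, 99):
            rule = glm.centile_rule(probs, c)
            assert rule.n_flagged / 10_000 == pytest.approx(1 - c / 100, abs=0.005)

    def test_invalid_centile_rejected(self):
        with pytest.raises(ValueError):
            glm.centile_rule([0.1, 0.2], 0)
        with pytest.raises(ValueError):
            glm.centile_rule([0.1, 0.2], 100)
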