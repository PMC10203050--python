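import itertools

import numpy as np
import pandas as pd
import pytest

from gxsex import EffectCovarianceMixture, hypothesis_grid
from gxsex.mixture import Component, HypothesisMatrixSet, MixtureResults

from conftest import make_sumstats


def draw_sumstats_from_component(n, U, scale=1.0, se=0.1, null_frac=0.0, seed=0):
    """Effect estimates drawn from one scaled component plus noise."""
    rng = np.random.default_rng(seed)
    vals, vecs = np.linalg.eigh(scale * np.asarray(U, dtype=float))
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None))) @ vecs.T
    b = rng.standard_normal((n, 2)) @ root
    b[rng.random(n) < null_frac] = 0.0
    ss = make_sumstats(n, seed=seed + 1, se_m=se, se_f=se)
    ss["beta_m"] = b[:, 0] + rng.normal(0, se, n)
    ss["beta_f"] = b[:, 1] + rng.normal(0, se, n)
    return ss


class TestHypothesisGrid:
    def test_default_has_66_labeled_components(self):
        grid = hypothesis_grid()
        assert len(grid) == 66
        classes = {c.magnitude_class for c in grid.components}
        assert classes == {"null", "M-only", "F-only", "M>F", "equal", "M<F"}

    def test_equal_pattern(self):
        grid = hypothesis_grid()
        c = grid.components[grid.index("r=1,q=1")]
        np.testing.assert_array_equal(c.matrix, [[1, 1], [1, 1]])
        assert c.magnitude_class == "equal"

    def test_negative_correlation_pattern_psd(self):
        grid = hypothesis_grid()
        c = grid.components[grid.index("r=-1,q=2")]
        np.testing.assert_array_equal(c.matrix, [[1, -2], [-2, 4]])
        np.testing.assert_allclose(sorted(np.linalg.eigvalsh(c.matrix)), [0, 5],
                                   atol=1e-12)

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            hypothesis_grid(correlations=(0.5, 0.5), ratios=(1.0,))

    def test_exactly_one_null_required(self):
        with pytest.raises(ValueError, match="null"):
            HypothesisMatrixSet([Component("a", np.eye(2), "equal")])


class TestFit:
    def test_single_component_simplex_corner(self):
        ss = draw_sumstats_from_component(200, [[1, 1], [1, 1]], seed=3)
        grid = HypothesisMatrixSet([
            Component("null", np.zeros((2, 2)), "null"),
            Component("eq", np.array([[1.0, 1], [1, 1]]), "equal",
                      correlation=1.0, ratio=1.0),
        ])
        res = EffectCovarianceMixture(ss, grid=grid).fit()
        w = res.component_weights()
        assert w["eq"] > 0.99

    def test_two_component_weight_recovery(self):
        # 50% null / 50% one known component: recovered within 0.05
        ss = draw_sumstats_from_component(2000, [[1, 1], [1, 1]],
                                          null_frac=0.5, se=0.2, seed=5)
        res = EffectCovarianceMixture(ss).fit()
        null_w = res.component_weights().iloc[0]
        assert null_w == pytest.approx(0.5, abs=0.05)

    def test_loglik_trace_monotone_and_simplex(self):
        ss = make_sumstats(150, seed=7)
        res = EffectCovarianceMixture(ss).fit()
        assert np.all(np.diff(res.trace) >= -1e-9 * np.abs(res.trace[0]))
        assert abs(res.pi.sum() - 1) < 1e-12 and (res.pi >= 0).all()

    def test_em_matches_grid_search_oracle(self):
        # independent oracle: two-stage simplex grid search over the
        # proportions of a 3-component mixture
        ss = draw_sumstats_from_component(200, [[1, 0.5], [0.5, 1]],
                                          null_frac=0.3, se=0.3, seed=9)
        grid = HypothesisMatrixSet([
            Component("null", np.zeros((2, 2)), "null"),
            Component("c1", np.array([[1.0, 0.5], [0.5, 1.0]]), "equal",
                      correlation=0.5, ratio=1.0),
            Component("c2", np.array([[1.0, 0.0], [0.0, 4.0]]), "M<F",
                      correlation=0.0, ratio=2.0),
        ])
        model = EffectCovarianceMixture(ss, grid=grid, scales=[1.0])
        res = model.fit()
        logL = model.loglik_matrix()
        mx = logL.max(axis=1)
        L = np.exp(logL - mx[:, None])
        shift = mx.sum()

        def grid_max(center, width, step):
            best = (-np.inf, None)
            lo = np.clip(center - width, 0, 1)
            g0 = np.arange(lo[0], min(center[0] + width, 1) + step / 2, step)
            g1 = np.arange(lo[1], min(center[1] + width, 1) + step / 2, step)
            pts = [(a, b, 1 - a - b) for a, b in itertools.product(g0, g1)
                   if 1 - a - b >= 0]
            P = np.array(pts)
            lls = np.log(L @ P.T).sum(axis=0) + shift
            k = int(np.argmax(lls))
            return lls[k], P[k]

        ll1, p1 = grid_max(np.array([0.5, 0.5]), 0.5, 0.01)
        ll2, p2 = grid_max(p1[:2], 0.012, 5e-4)
        ll_em = res.trace[-1]
        assert ll_em >= ll2 - 1e-4
        assert abs(ll_em - ll2) < 5e-3

    def test_resampled_determinism_and_degenerate_block(self):
        ss = make_sumstats(60, seed=11)
        model = EffectCovarianceMixture(ss)
        blocks = np.arange(60) % 12
        r1 = model.fit_resampled(blocks, n_repeats=5, seed=42)
        r2 = model.fit_resampled(blocks, n_repeats=5, seed=42)
        np.testing.assert_array_equal(r1.pi, r2.pi)
        # one block containing one SNP: averaged pi equals the single fit
        one = EffectCovarianceMixture(ss.iloc[:1])
        ra = one.fit_resampled(np.array([0]), n_repeats=3, seed=0)
        rb = one.fit()
        np.testing.assert_allclose(ra.pi, rb.pi, atol=1e-9)

    def test_repeat_variance_decreases_with_blocks(self):
        ss = draw_sumstats_from_component(1000, [[1, 1], [1, 1]], se=0.3, seed=13)
        model = EffectCovarianceMixture(ss)
        sds = []
        for nb in (20, 200):
            blocks = np.arange(1000) % nb
            res = model.fit_resampled(blocks, n_repeats=15, seed=1)
            eq = [res.component_weights(p)["r=1,q=1"] for p in res.per_repeat]
            sds.append(np.std(eq))
        assert sds[1] < sds[0]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            EffectCovarianceMixture(make_sumstats(5).iloc[:0])


class TestWeightSummary:
    @staticmethod
    def _results_with(weights):
        ss = make_sumstats(10)
        grid = HypothesisMatrixSet([
            Component("null", np.zeros((2, 2)), "null"),
            Component("equal", np.array([[1.0, 1], [1, 1]]), "equal", 1.0, 1.0),
            Component("mgtf", np.array([[1.0, 0.25], [0.25, 0.25]]), "M>F", 0.5, 0.5),
            Component("mltf", np.array([[1.0, 1], [1, 4.0]]), "M<F", 0.5, 2.0),
            Component("monly", np.array([[1.0, 0], [0, 0]]), "M-only"),
        ])
        model = EffectCovarianceMixture(ss, grid=grid, scales=[1.0])
        pi = np.array([weights.get(c.label, 0.0) for c in grid.components])
        return MixtureResults(model, pi)

    def test_nonnull_normalization_arithmetic(self):
        res = self._results_with({"null": 0.5, "equal": 0.3, "mgtf": 0.15,
                                  "mltf": 0.05})
        ws = res.weight_summary()
        assert ws.nonnull["equal"] == pytest.approx(0.6)
        assert ws.nonnull["mgtf"] == pytest.approx(0.3)
        assert ws.nonnull["mltf"] == pytest.approx(0.1)
        assert ws.sex_biased_amplification == pytest.approx(0.2)

    def test_male_larger_share_like_testosterone(self):
        # 32% non-null weight total, nearly all on male-larger matrices
        res = self._results_with({"null": 0.68, "mgtf": 0.2484, "monly": 0.06528,
                                  "mltf": 0.0064, "equal": 0.00032})
        ws = res.weight_summary()
        male_larger = ws.category_nonnull["M>F"] + ws.category_nonnull["M-only"]
        assert male_larger == pytest.approx(0.98, abs=0.005)
        assert ws.category_nonnull["M-only"] == pytest.approx(0.204, abs=0.002)

    def test_all_null_flagged(self):
        res = self._results_with({"null": 1.0})
        ws = res.weight_summary()
        assert ws.nonnull is None and ws.sex_biased_amplification is None


class TestPosterior:
    @staticmethod
    def _single_component_model(ss, U, scale=1.0):
        grid = HypothesisMatrixSet([
            Component("null", np.zeros((2, 2)), "null"),
            Component("c", np.asarray(U, dtype=float), "equal", 0.0, 1.0),
        ])
        return EffectCovarianceMixture(ss, grid=grid, scales=[scale])

    def test_conjugate_closed_form(self):
        # single component U = I, S = I, beta_hat = (2, 0): posterior mean
        # U (U + S)^{-1} beta_hat = (1, 0), sd = sqrt(1/2)
        ss = make_sumstats(1, se_m=1.0, se_f=1.0)
        ss.loc[0, ["beta_m", "beta_f"]] = [2.0, 0.0]
        model = self._single_component_model(ss, np.eye(2))
        res = MixtureResults(model, np.array([0.0, 1.0]))
        post = res.posterior_effects()
        assert post["post_beta_m"][0] == pytest.approx(1.0)
        assert post["post_beta_f"][0] == pytest.approx(0.0)
        assert post["post_sd_m"][0] == pytest.approx(np.sqrt(0.5))

    def test_no_noise_limit_returns_estimates(self):
        ss = make_sumstats(20, seed=3, se_m=1e-5, se_f=1e-5)
        model = self._single_component_model(ss, np.eye(2), scale=4.0)
        res = MixtureResults(model, np.array([0.0, 1.0]))
        post = res.posterior_effects()
        np.testing.assert_allclose(post["post_beta_m"], ss["beta_m"], atol=1e-4)

    def test_null_only_shrinks_to_zero(self):
        ss = make_sumstats(20, seed=4)
        model = self._single_component_model(ss, np.eye(2))
        res = MixtureResults(model, np.array([1.0, 0.0]))
        post = res.posterior_effects()
        assert np.allclose(post["post_beta_m"], 0) and np.allclose(post["post_beta_f"], 0)

    def test_shrinkage_bound(self):
        ss = make_sumstats(100, seed=5)
        res = EffectCovarianceMixture(ss).fit()
        post = res.posterior_effects()
        assert (np.abs(post["post_beta_m"]) <= np.abs(ss["beta_m"]) + 3 * ss["se_m"]).all()
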