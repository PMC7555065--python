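import numpy as np
import pytest
from scipy import stats

from speechtrack import regression_suite as rs
from speechtrack import tracking_stats as ts
from speechtrack.fragments import Fragment, FragmentSet
from speechtrack.preprocess import ChannelMeta, HFBMatrix


class TestLagAlign:
    def test_zero_lag_identity(self, rng):
        x = rng.standard_normal(400)
        np.testing.assert_array_equal(rs.lag_align(x, 0.0), x)

    def test_100ms_shift(self):
        x = np.arange(400.0)
        out = rs.lag_align(x, 100.0)
        assert len(out) == 390
        np.testing.assert_array_equal(out, x[10:])

    def test_negative_clamped(self, rng):
        x = rng.standard_normal(400)
        np.testing.assert_array_equal(rs.lag_align(x, -200.0), x)

    def test_lag_too_large(self):
        with pytest.raises(ValueError):
            rs.lag_align(np.zeros(10), 200.0)

    def test_alignment_improves_zero_lag_correlation(self, rng):
        # planted 300 ms coupling: alignment must not hurt zero-lag Spearman
        env = np.cumsum(rng.standard_normal(400))
        y = np.empty(400)
        y[30:] = env[:-30]
        y[:30] = rng.standard_normal(30)
        before = ts.spearman_rho(env, y)
        after = ts.spearman_rho(env[: 400 - 30], rs.lag_align(y, 300.0))
        assert after >= before


class TestOnOffOLS:
    def test_exact_fit(self):
        x = np.tile([0.0, 1.0], 200)
        y = 2.0 * x
        fit = rs.onoff_ols(y, x)
        assert fit.beta[1] == pytest.approx(2.0)
        assert fit.f > 1e12  # large finite
        assert np.isfinite(fit.f)

    def test_null_slope_near_zero(self, rng):
        x = np.tile([0.0, 1.0], 500)
        y = rng.standard_normal(1000)
        fit = rs.onoff_ols(y, x)
        assert abs(fit.beta[1]) < 0.3

    def test_consistency_at_paper_scale(self, rng):
        n = 46_000
        x = (rng.random(n) > 0.5).astype(float)
        y = x + rng.standard_normal(n)
        fit = rs.onoff_ols(y, x)
        assert fit.beta[1] == pytest.approx(1.0, abs=0.02)

    def test_constant_regressor_error(self):
        with pytest.raises(ValueError):
            rs.onoff_ols(np.arange(10.0), np.ones(10))

    def test_residual_orthogonality(self, rng):
        n = 500
        x = (rng.random(n) > 0.4).astype(float)
        y = 0.5 * x + rng.standard_normal(n)
        fit = rs.onoff_ols(y, x)
        assert abs(fit.residuals @ x) < 1e-6 * n
        assert abs(fit.residuals.sum()) < 1e-6 * n

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 300
        x = (rng.random(n) > 0.5).astype(float)
        y = 0.8 * x + rng.standard_normal(n)
        fit = rs.onoff_ols(y, x)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-10)
        assert fit.f == pytest.approx(ref.fvalue)
        np.testing.assert_allclose(fit.t, ref.tvalues, atol=1e-8)


class TestPermutationFTest:
    def _blocks(self, rng, nb=10, length=50, coupled=False):
        xb = [(rng.random(length) > 0.5).astype(float) for _ in range(nb)]
        if coupled:
            yb = [x + 0.5 * rng.standard_normal(length) for x in xb]
        else:
            yb = [rng.standard_normal(length) for _ in range(nb)]
        return yb, xb

    def test_seed_determinism(self, rng):
        yb, xb = self._blocks(rng)
        n1 = rs.permutation_f_test(yb, xb, n_perm=200, alpha=0.05, seed=3)
        n2 = rs.permutation_f_test(yb, xb, n_perm=200, alpha=0.05, seed=3)
        assert n1.threshold == n2.threshold
        np.testing.assert_array_equal(n1.f_values, n2.f_values)

    def test_power(self, rng):
        yb, xb = self._blocks(rng, coupled=True)
        null = rs.permutation_f_test(yb, xb, n_perm=500, alpha=0.05, seed=0)
        assert null.significant

    def test_fast_path_equals_naive_refit(self, rng):
        yb, xb = self._blocks(rng, nb=6, length=30)
        n_perm = 50
        res = rs.permutation_f_test(yb, xb, n_perm=n_perm, alpha=0.05, seed=9)
        # independent oracle: same permutation stream, full refit per draw
        r = np.random.default_rng(9)
        y = np.concatenate(yb)
        expected = np.empty(n_perm)
        for i in range(n_perm):
            order = r.permutation(len(xb))
            xp = np.concatenate([xb[j] for j in order])
            expected[i] = rs.onoff_ols(y, xp).f
        np.testing.assert_allclose(res.f_values, expected, rtol=1e-9)

    def test_unequal_block_lengths_supported(self, rng):
        yb = [rng.standard_normal(30), rng.standard_normal(40), rng.standard_normal(50)]
        xb = [(rng.random(len(b)) > 0.5).astype(float) for b in yb]
        null = rs.permutation_f_test(yb, xb, n_perm=100, alpha=0.05, seed=1)
        assert null.threshold >= null.f_values.min()
        assert null.threshold <= null.f_values.max()

    def test_n_perm_warning(self, rng):
        yb, xb = self._blocks(rng, nb=4)
        with pytest.warns(UserWarning):
            rs.permutation_f_test(yb, xb, n_perm=100, alpha=0.001, seed=0)

    def test_single_fragment_error(self, rng):
        with pytest.raises(ValueError):
            rs.permutation_f_test([rng.standard_normal(10)], [np.ones(10)], n_perm=10, alpha=0.5)


class TestOnOffConditionContrast:
    def test_equal_populations(self, rng):
        t, p = rs.onoff_condition_contrast(rng.standard_normal(30), rng.standard_normal(30))
        assert abs(t) < 3.5

    def test_planted_difference(self, rng):
        t, p = rs.onoff_condition_contrast(rng.normal(1, 0.1, 20), rng.normal(0, 0.1, 20))
        assert t > 0 and p < 1e-6

    def test_single_electrode_error(self):
        with pytest.raises(ValueError):
            rs.onoff_condition_contrast([1.0], [0.0, 0.5])


class TestPartialSpearman:
    def test_target_equals_control_error(self, rng):
        y = rng.standard_normal(100)
        c = rng.standard_normal(100)
        with pytest.raises(ValueError):
            rs.partial_spearman(y, c, c)

    def test_control_driven_y_near_zero(self, rng):
        c = rng.standard_normal(500)
        y = 2.0 * c  # y entirely control-driven
        t = rng.standard_normal(500)
        assert abs(rs.partial_spearman(y, t, c)) < 0.1

    def test_independent_control_matches_simple(self, rng):
        n = 400
        t = rng.standard_normal(n)
        y = 0.6 * t + 0.8 * rng.standard_normal(n)
        c = rng.standard_normal(n)  # independent of both
        simple = ts.spearman_rho(y, t)
        partial = rs.partial_spearman(y, t, c)
        assert partial == pytest.approx(simple, abs=0.02)

    def test_constant_series_error(self):
        with pytest.raises(ValueError):
            rs.partial_spearman(np.ones(10), np.arange(10.0), np.arange(10.0) ** 2)


class TestPitchEnvelopeInteraction:
    def _fragset(self):
        return FragmentSet(
            [Fragment(0.0, 4.0, "speech"), Fragment(4.0, 4.0, "speech"),
             Fragment(8.0, 4.0, "nonspeech"), Fragment(12.0, 4.0, "nonspeech")]
        )

    def test_unvoiced_fragments_excluded(self, rng):
        env = rng.random(1600) + 0.1
        pitch = np.zeros(1600)  # no voicing anywhere
        out = rs.pitch_envelope_interaction(env, pitch, self._fragset())
        assert len(out["speech"]["rho"]) == 0
        assert out["speech"]["excluded_fragments"] == [0, 1]

    def test_monotone_relation_rho_one(self, rng):
        pitch = rng.random(1600) + 1.0
        env = np.log(pitch)  # strictly monotone function of pitch
        out = rs.pitch_envelope_interaction(env, pitch, self._fragset())
        np.testing.assert_allclose(out["speech"]["rho"], 1.0)

    def test_bundle_speech_correlation_positive(self, bundle):
        out = rs.pitch_envelope_interaction(
            np.asarray(bundle.feats.envelope), np.asarray(bundle.feats.pitch), bundle.fragset
        )
        # shared syllabic gating implies positive envelope-pitch correlation
        assert out["speech"]["mean_rho"] > 0
        assert out["speech"]["p_vs_zero"] < 0.001


class TestAuditoryOLSResiduals:
    def _hfb_and_frags(self, rng, y=None):
        n_frames = 1600
        vals = rng.standard_normal((2, n_frames)) if y is None else y
        meta = [ChannelMeta("e0"), ChannelMeta("e1")]
        hfb = HFBMatrix(vals, meta, zscored=True)
        frags = FragmentSet([Fragment(0.0, 4.0, "speech"), Fragment(4.0, 4.0, "speech"),
                             Fragment(8.0, 4.0, "speech"), Fragment(12.0, 4.0, "speech")])
        return hfb, frags

    def test_exact_linear_combination(self, rng):
        n = 1600
        env = rng.random(n)
        onoff = (rng.random(n) > 0.4).astype(float)
        pitch = rng.random(n) * 200
        y = np.vstack([1.0 + 2 * env - onoff + 0.01 * pitch,
                       0.5 - env + 3 * onoff + 0.02 * pitch])
        hfb, frags = self._hfb_and_frags(rng, y)
        out = rs.auditory_ols_residuals(hfb, env, onoff, pitch, frags, "speech")
        for eid in out["electrodes"]:
            assert np.var(out["residuals"][eid]) < 1e-10

    def test_independent_response_keeps_variance(self, rng):
        n = 1600
        env = rng.random(n)
        onoff = (rng.random(n) > 0.4).astype(float)
        pitch = rng.random(n) * 200
        hfb, frags = self._hfb_and_frags(rng)
        out = rs.auditory_ols_residuals(hfb, env, onoff, pitch, frags, "speech")
        y = hfb.values[0, hfb.fragment_frames(frags)]
        assert np.var(out["residuals"]["e0"]) == pytest.approx(np.var(y), rel=0.05)

    def test_collinear_design_error(self, rng):
        n = 1600
        env = rng.random(n)
        hfb, frags = self._hfb_and_frags(rng)
        with pytest.raises(ValueError, match="collinear"):
            rs.auditory_ols_residuals(hfb, env, (env > 0.5).astype(float), 2.0 * env, frags, "speech")

    def test_planted_coupling_shrinks_residual_means(self, rng):
        n = 1600
        env = rng.random(n)
        onoff = (rng.random(n) > 0.4).astype(float)
        pitch = rng.random(n) * 200
        y = np.vstack([3.0 * env + 0.3 * rng.standard_normal(n),
                       rng.standard_normal(n)])
        hfb, frags = self._hfb_and_frags(rng, y)
        out = rs.auditory_ols_residuals(hfb, env, onoff, pitch, frags, "speech")
        full = hfb.values[0, hfb.fragment_frames(frags)]
        frag_means_full = [abs(full[sl].mean() - full.mean()) for sl in out["fragment_slices"]]
        resid = out["residuals"]["e0"]
        frag_means_resid = [abs(resid[sl].mean()) for sl in out["fragment_slices"]]
        assert np.mean(frag_means_resid) < np.mean(frag_means_full)


def brute_force_kruskal_h(groups):
    """Textbook rank formula with tie correction, computed from scratch."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = stats.rankdata(all_vals)
    pos = 0
    h = 0.0
    for g in groups:
        r = ranks[pos : pos + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        pos += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(all_vals, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


class TestRankGroupComparison:
    def _groups(self, rng, shift=0.0):
        return {
            "speech_full": rng.standard_normal(12) + shift,
            "speech_resid": rng.standard_normal(12),
            "nonspeech_full": rng.standard_normal(12),
            "nonspeech_resid": rng.standard_normal(12),
        }

    def test_identical_groups(self, rng):
        base = rng.standard_normal(10)
        groups = {k: base.copy() for k in
                  ("speech_full", "speech_resid", "nonspeech_full", "nonspeech_resid")}
        out = rs.rank_group_comparison(groups)
        assert out.h == pytest.approx(0.0, abs=1e-10)
        assert all(p > 0.99 for p in out.dunn_p.values())

    def test_small_instance_brute_force(self, rng):
        groups = [rng.standard_normal(4), rng.standard_normal(4), rng.standard_normal(4)]
        h_expected = brute_force_kruskal_h(groups)
        h_scipy, _ = stats.kruskal(*groups)
        assert h_scipy == pytest.approx(h_expected, abs=1e-10)
        named = {"speech_full": groups[0], "speech_resid": groups[1],
                 "nonspeech_full": groups[2], "nonspeech_resid": rng.standard_normal(4)}
        out = rs.rank_group_comparison(named)
        assert out.h == pytest.approx(
            brute_force_kruskal_h(list(named.values())), abs=1e-10
        )

    def test_planted_condition_main_effect(self, rng):
        groups = {
            "speech_full": rng.standard_normal(20) + 3.0,
            "speech_resid": rng.standard_normal(20) + 3.0,
            "nonspeech_full": rng.standard_normal(20),
            "nonspeech_resid": rng.standard_normal(20),
        }
        out = rs.rank_group_comparison(groups)
        assert out.anova_p["condition"] < 1e-6
        assert out.anova_p["interaction"] > 0.01

    def test_group_too_small_error(self):
        with pytest.raises(ValueError):
            rs.rank_group_comparison({"speech_full": [1.0], "speech_resid": [1.0, 2.0],
                                      "nonspeech_full": [1.0, 2.0], "nonspeech_resid": [1.0, 2.0]})


class TestCovariateControl:
    def test_independent_labels_retain_electrodes(self, bundle):
        # under independent hand labels every originally significant electrode
        # stays significant and the t maps barely move; the Wilcoxon comparison
        # is reported (a residualization of one covariate inflates |t| by an
        # O(1/n_fragments) amount, so its p value is not asserted here)
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, len(bundle.fragset))
        out = rs.covariate_control(bundle.hfb, bundle.fragset, labels, bundle.envelope,
                                   rerun_tracking=False)
        assert set(out["preference_updated"].significant_ids()) >= set(out["mask"])
        sig = out["preference_original"].significant
        rel = np.abs(out["preference_updated"].t[sig] - out["preference_original"].t[sig])
        rel = rel / np.abs(out["preference_original"].t[sig])
        assert rel.max() < 0.10
        assert "wilcoxon_preference" in out

    def test_constant_labels_skips_regression(self, bundle):
        labels = np.ones(len(bundle.fragset), dtype=int)
        out = rs.covariate_control(bundle.hfb, bundle.fragset, labels, bundle.envelope,
                                   rerun_tracking=False)
        assert out["hand_regression_skipped"]

    def test_hand_duplicated_as_signal_collapses(self, rng):
        # neural signal equal to the hand regressor -> residual ~ 0
        frags = FragmentSet([Fragment(i * 4.0, 4.0, "speech") for i in range(3)]
                            + [Fragment(12.0 + i * 4.0, 4.0, "nonspeech") for i in range(3)])
        labels = np.array([0, 1, 2, 0, 1, 2])
        n_frames = 2400
        vals = np.zeros((2, n_frames))
        for f, lab in zip(frags, labels):
            i0 = int(f.onset * 100)
            vals[0, i0 : i0 + 400] = float(lab)
        vals[0] += 1e-6 * rng.standard_normal(n_frames)
        vals[1] = rng.standard_normal(n_frames)
        hfb = HFBMatrix(vals, [ChannelMeta("e0"), ChannelMeta("e1")], zscored=True)
        env = rng.random(n_frames)
        out = rs.covariate_control(hfb, frags, labels, env)
        resid = out["residual_hfb"].values[0, hfb.fragment_frames(frags)]
        assert np.var(resid) < 1e-10

    def test_label_count_mismatch(self, bundle):
        with pytest.raises(ValueError):
            rs.covariate_control(bundle.hfb, bundle.fragset, np.array([0, 1]), bundle.envelope)


class TestChi2:
    def test_proportional_rows_zero(self):
        obs = np.array([[10, 20, 30], [20, 40, 60]])
        assert rs.chi2_independence(obs).chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_error(self):
        with pytest.raises(ValueError):
            rs.chi2_independence(np.array([[0, 0], [1, 2]]))

    def test_yates_requires_2x2(self):
        with pytest.raises(ValueError):
            rs.chi2_independence(np.array([[1, 2, 3], [4, 5, 6]]), yates=True)

    def test_non_integer_counts_error(self):
        with pytest.raises(ValueError):
            rs.chi2_independence(np.array([[1.5, 2], [3, 4]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        r = np.random.default_rng(seed)
        obs = r.integers(5, 80, size=(r.integers(2, 4), r.integers(2, 4)))
        ours = rs.chi2_independence(obs)
        ref_chi2, ref_p, ref_df, _ = stats.chi2_contingency(obs, correction=False)
        assert ours.chi2 == pytest.approx(ref_chi2)
        assert ours.df == ref_df
        assert ours.p == pytest.approx(ref_p)

    def test_yates_matches_scipy_2x2(self):
        obs = np.array([[12, 34], [45, 23]])
        ours = rs.chi2_independence(obs, yates=True)
        ref_chi2, *_ = stats.chi2_contingency(obs, correction=True)
        assert ours.chi2 == pytest.approx(ref_chi2)
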