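"""HRF, design matrix, prewhitened robust GLM, group model, FDR."""

import numpy as np
import pytest
from scipy import stats

from nirspain.activation import (
    DesignMatrix,
    FirstLevelGLM,
    GroupActivation,
    build_design,
    canonical_hrf,
    fdr_correct,
    fit_first_level,
    fit_group,
)
from nirspain.probe import EventDesign


class TestCanonicalHRF:
    def test_peak_at_six_seconds(self):
        for rate in (2.0, 25.0):
            h = canonical_hrf(rate)
            assert np.argmax(h) / rate == pytest.approx(6.0, abs=1.0 / rate)

    def test_unit_peak_and_zero_origin(self):
        h = canonical_hrf(25.0)
        assert h.max() == pytest.approx(1.0)
        assert h[0] == pytest.approx(0.0, abs=1e-12)

    def test_has_undershoot(self):
        h = canonical_hrf(2.0)
        assert h.min() < -0.01

    def test_integral_positive_finite(self):
        h = canonical_hrf(10.0)
        integral = np.trapezoid(h, dx=0.1)
        assert 0 < integral < np.inf


class TestBuildDesign:
    def test_no_events_gives_nuisance_only(self):
        ev = EventDesign(np.array([]), np.array([]), [])
        d = build_design(ev, 100, 2.0)
        assert d.names == ["intercept", "drift"]

    def test_single_trial_column_peaks_after_onset(self):
        ev = EventDesign([20.0], [16.0], ["tqst_trial"])
        d = build_design(ev, 300, 2.0)
        col = d.X[:, d.column("tqst_trial")]
        peak_t = np.argmax(col) / 2.0
        assert 23.0 < peak_t < 46.0  # onset + HRF lag, before washout

    def test_identical_conditions_rank_deficient(self):
        # two conditions with identical onsets/durations: perfect collinearity
        ev = EventDesign(
            np.array([10.0, 10.0, 40.0, 40.0]),
            np.array([5.0] * 4),
            ["a", "b", "a", "b"],
        )
        with pytest.raises(ValueError, match="collinear"):
            build_design(ev, 200, 2.0)

    def test_rate_invariant_amplitude(self):
        """dt-scaled convolution: regressor height does not depend on rate."""
        ev = EventDesign([20.0], [16.0], ["t"])
        lo = build_design(ev, 200, 2.0)
        hi = build_design(ev, 2500, 25.0)
        assert lo.X[:, 0].max() == pytest.approx(hi.X[:, 0].max(), rel=0.02)


def _sim_design(rate=2.0, n_trials=8, rest=10.0):
    from nirspain.simulate import simulate_tqst_events

    ev = simulate_tqst_events(np.full(n_trials, 46.0), rest_s=rest)
    n = int(np.ceil((ev.end_time() + rest) * rate))
    return build_design(ev, n, rate)


class TestFirstLevelGLM:
    def test_noiseless_beta_recovered(self):
        design = _sim_design()
        y = 1.0 * design.X[:, 0] + 0.2  # beta=1 on the condition, intercept
        res = fit_first_level(y[None, :], design)
        assert abs(res.beta[0, 0] - 1.0) < 1e-6

    def test_reduces_to_ols_on_white_noise(self, rng):
        design = _sim_design()
        y = 0.3 * design.X[:, 0] + rng.standard_normal(design.n_samples)
        res = fit_first_level(
            y[None, :], design, robust=False, max_ar_order=0
        )
        ols, *_ = np.linalg.lstsq(design.X, y, rcond=None)
        assert np.max(np.abs(res.beta[0] - ols)) < 1e-8

    def test_common_rescaling_equivariance(self, rng):
        """Scaling data and design together leaves beta unchanged."""
        design = _sim_design()
        y = 0.5 * design.X[:, 0] + 0.1 * rng.standard_normal(design.n_samples)
        res1 = fit_first_level(y[None, :], design)
        scaled = DesignMatrix(
            X=design.X * 3.7, names=design.names,
            sampling_rate=design.sampling_rate,
        )
        res2 = fit_first_level(3.7 * y[None, :], scaled)
        assert np.allclose(res1.beta, res2.beta, atol=1e-8)

    def test_ar1_noise_beta_unbiased(self, rng):
        design = _sim_design()
        from scipy.signal import lfilter

        betas = []
        for _ in range(30):
            e = lfilter([1], [1, -0.6],
                        rng.standard_normal(design.n_samples)) * 0.3
            y = 0.5 * design.X[:, 0] + e
            betas.append(fit_first_level(y[None, :], design).beta[0, 0])
        assert np.mean(betas) == pytest.approx(0.5, abs=0.05)

    def test_nonconvergence_flagged_not_fatal(self, rng):
        design = _sim_design()
        y = rng.standard_normal(design.n_samples)
        glm = FirstLevelGLM(max_iter=1)
        with pytest.warns(RuntimeWarning, match="tolerance"):
            glm.fit(design, y[None, :])
        assert not glm.converged_[0]
        assert np.isfinite(glm.coef_).all()


class TestGroupActivation:
    def _first_level(self, beta_val, subject, visit=1, se=0.1):
        from nirspain.activation import FirstLevelResult

        p = 2
        n_ch = 3
        beta = np.column_stack(
            [np.full(n_ch, beta_val), np.zeros(n_ch)]
        )
        cov = np.tile(np.diag([se**2, se**2]), (n_ch, 1, 1))
        return FirstLevelResult(
            subject=subject, names=["tqst_trial", "intercept"], beta=beta,
            cov=cov, resid_var=np.ones(n_ch), ar_coefs=[np.array([])] * n_ch,
            weight_mean=np.ones(n_ch), dof=np.full(n_ch, 100.0),
            converged=np.ones(n_ch, bool), visit=visit,
        )

    def test_identical_betas_give_exact_effect(self):
        fls = [self._first_level(0.7, f"s{i}", v)
               for i in range(4) for v in (1, 2)]
        res = fit_group(fls)
        assert np.allclose(res.effect, 0.7)
        assert np.allclose(res.random_var, 0.0, atol=1e-12)
        assert np.all(res.pvalues < 1e-10)

    def test_matches_brute_force_gls_on_toy_input(self, rng):
        """Closed-form REML t equals GLS with the estimated components."""
        # clear between-subject spread keeps the REML estimate interior
        values = 0.2 * rng.standard_normal(6) + np.repeat(
            [0.5, 1.0, 1.8], 2
        )
        subjects = np.array(["a", "a", "b", "b", "c", "c"])
        from nirspain.activation import _balanced_random_intercept

        b, s, tau2, df = _balanced_random_intercept(values, subjects)
        # brute force: V = tau2*J + sigma2*I per subject block
        within = np.mean(
            [np.var(values[subjects == u], ddof=1) for u in "abc"]
        )
        V = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if subjects[i] == subjects[j]:
                    V[i, j] = tau2 + (within if i == j else 0.0)
        Vinv = np.linalg.inv(V)
        ones = np.ones(6)
        var_gls = 1.0 / (ones @ Vinv @ ones)
        b_gls = var_gls * (ones @ Vinv @ values)
        assert b == pytest.approx(b_gls, abs=1e-8)
        assert s == pytest.approx(np.sqrt(var_gls), abs=1e-8)

    def test_agrees_with_mixedlm(self, rng):
        offsets = np.repeat(rng.standard_normal(6), 2)  # interior tau2
        values = rng.standard_normal(12) * 0.3 + 1.0 + offsets
        subjects = np.repeat([f"s{i}" for i in range(6)], 2)
        from nirspain.activation import (
            _balanced_random_intercept,
            _mixedlm_fit,
        )

        b1, s1, _, _ = _balanced_random_intercept(values, subjects)
        b2, s2, _, _, fb = _mixedlm_fit(
            values, subjects, np.array(["TMB"] * 12), "1"
        )
        assert not fb
        assert b1 == pytest.approx(b2, rel=1e-3)
        assert s1 == pytest.approx(s2, rel=0.05)

    def test_group_recovery_coverage(self, rng):
        """Mean of subject effects recovered within +-0.15 most of the time."""
        hits = 0
        for rep in range(40):
            fls = [
                self._first_level(
                    1.0 + 0.2 * rng.standard_normal()
                    + 0.1 * rng.standard_normal(),
                    f"s{i}",
                )
                for i in range(20)
            ]
            res = fit_group(fls)
            hits += abs(res.effect[0] - 1.0) <= 0.15
        assert hits / 40 >= 0.85

    def test_too_few_subjects_rejected(self):
        fls = [self._first_level(1.0, "a"), self._first_level(1.0, "b")]
        with pytest.raises(ValueError, match="3 subjects"):
            fit_group(fls)

    def test_eq5_identity(self, rng):
        """|t| equals |effect| / sqrt(contrast' Cov contrast) per channel."""
        fls = [self._first_level(1.0 + rng.standard_normal() * 0.3, f"s{i}")
               for i in range(8)]
        res = fit_group(fls)
        assert np.allclose(np.abs(res.tvalues),
                           np.abs(res.effect) / res.se)


class TestFDR:
    def test_all_ones_no_rejections(self):
        qvals, reject = fdr_correct([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_hand_stepped_oracle(self):
        """BH on {0.001, 0.5, 0.9}: only the first rejected, q1 = 0.003."""
        qvals, reject = fdr_correct([0.001, 0.5, 0.9], q=0.05)
        assert list(reject) == [True, False, False]
        assert qvals[0] == pytest.approx(0.003)
        assert qvals[1] == pytest.approx(0.75)
        assert qvals[2] == pytest.approx(0.9)

    def test_q_never_below_p(self, rng):
        p = rng.random(45)
        qvals, _ = fdr_correct(p)
        assert np.all(qvals >= p - 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([])

    def test_null_simulation_controls_fdr(self, rng):
        rejections = 0
        for _ in range(300):
            p = rng.random(45)
            _, reject = fdr_correct(p, q=0.05)
            rejections += reject.any()
        assert rejections / 300 <= 0.05 + 0.03
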