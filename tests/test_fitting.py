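"""Model-fitting tests: identifiability, MLE noise, AIC, recovery harness."""

import time

import numpy as np
import pandas as pd
import pytest

from regimeshift import (
    NoiseModel,
    PopulationSpec,
    SubjectParams,
    aic,
    compare_models,
    fit_cohort,
    fit_mle_noise,
    fit_nls,
    generate_design,
    generate_trials,
    sample_subject_params,
    simulate_estimates,
    simulate_missing,
)
from regimeshift.fitting import FitResult, fits_to_frame

Q = np.array([0.01, 0.05, 0.1])


def _random_params(variant, rng):
    a_shape = (2, 3) if variant in ("sn_sigdep_alpha", "sn_sigdep_alphabeta") else (3,)
    b_shape = (2, 3) if variant in ("sn_sigdep_beta", "sn_sigdep_alphabeta") else (3,)
    alpha = rng.uniform(0.2, 4.0, a_shape)
    alpha = np.minimum(alpha, 0.9 / Q)
    beta = rng.uniform(0.2, 2.5, b_shape)
    return SubjectParams(variant, alpha, beta)


def _simulate(params, rng, n_blocks=2, sigma=0.0, clip=True):
    des = generate_design(n_blocks, rng=rng)
    seqs = generate_trials(des, rng=rng)
    return simulate_estimates(
        params, des, seqs, NoiseModel.homoscedastic(sigma), rng, clip=clip
    )


class TestNoiselessRoundTrip:
    @pytest.mark.parametrize(
        "variant",
        ["sn_original", "sn_sigdep_beta", "sn_sigdep_alpha", "sn_sigdep_alphabeta"],
    )
    def test_recovers_truth_to_optimizer_tolerance(self, variant):
        """simulate(params, sigma=0) -> fit -> params, <= 1e-4 absolute,
        for 20 random parameter sets per variant."""
        rng = np.random.default_rng(101)
        for _ in range(20):
            truth = _random_params(variant, rng)
            data = _simulate(truth, rng, n_blocks=2)
            fit = fit_nls(data, variant, rng=rng)
            assert fit.converged
            assert fit.params.alpha == pytest.approx(truth.alpha, abs=1e-4)
            assert fit.params.beta == pytest.approx(truth.beta, abs=1e-4)


class TestFitNls:
    def test_bayesian_data_recovers_unit_weights(self, rng):
        truth = SubjectParams("sn_original", np.ones(3), np.ones(3))
        data = _simulate(truth, rng, n_blocks=11, sigma=0.05)
        fit = fit_nls(data, "sn_original", rng=rng)
        assert fit.params.alpha == pytest.approx(1.0, abs=0.4)
        assert fit.params.beta == pytest.approx(1.0, abs=0.25)

    def test_full_design_fit_under_ten_seconds(self, rng):
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=11, sigma=0.15)
        t0 = time.perf_counter()
        fit = fit_nls(data, "sn_original", rng=rng)
        assert time.perf_counter() - t0 < 10.0
        assert fit.converged and fit.n_obs == 990

    def test_invariant_to_trial_order(self, rng):
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=3, sigma=0.1)
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f1 = fit_nls(data, rng=np.random.default_rng(5))
        f2 = fit_nls(shuffled, rng=np.random.default_rng(5))
        assert f1.params.alpha == pytest.approx(f2.params.alpha, abs=1e-9)
        assert f1.params.beta == pytest.approx(f2.params.beta, abs=1e-9)

    def test_missing_periods_are_dropped(self, rng):
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=11, sigma=0.1)
        lost = simulate_missing(data, 0.05, rng)
        fit_full = fit_nls(data, rng=np.random.default_rng(5))
        fit_miss = fit_nls(lost, rng=np.random.default_rng(5))
        assert fit_miss.n_obs == int((~lost["missing"]).sum()) < 990
        # 5% missing barely perturbs the estimates
        assert fit_miss.params.alpha == pytest.approx(fit_full.params.alpha, abs=0.3)
        assert fit_miss.params.beta == pytest.approx(fit_full.params.beta, abs=0.3)

    def test_rejects_bayes_variant_and_empty_data(self, rng):
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=1)
        with pytest.raises(ValueError):
            fit_nls(data, "bayes")
        data["missing"] = True
        with pytest.raises(ValueError):
            fit_nls(data, "sn_original")


class TestMleNoise:
    def test_sigma_hat_consistent_on_unclipped_data(self, rng):
        """With sigma = 0.15 and the Gaussian model exactly true (no
        boundary truncation), sigma_hat lands in [0.14, 0.16]."""
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=11, sigma=0.15, clip=False)
        fit = fit_mle_noise(data, rng=rng)
        assert 0.14 <= fit.sigma_noise_hat <= 0.16
        assert np.isfinite(fit.log_likelihood) and np.isfinite(fit.aic)

    def test_agrees_with_nls_point_estimates(self, rng):
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=3, sigma=0.1)
        f_nls = fit_nls(data, rng=np.random.default_rng(2))
        f_mle = fit_mle_noise(data, rng=np.random.default_rng(2))
        assert f_mle.params.alpha == pytest.approx(f_nls.params.alpha, abs=1e-3)
        assert f_mle.params.beta == pytest.approx(f_nls.params.beta, abs=1e-3)

    def test_clipping_biases_sigma_hat_downward(self, rng):
        """Boundary truncation shrinks residual spread, so sigma_hat on
        clipped data sits below the generating sigma."""
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=11, sigma=0.3, clip=True)
        fit = fit_mle_noise(data, rng=rng)
        assert fit.sigma_noise_hat < 0.3


class TestAic:
    def test_parameter_penalty_arithmetic(self, rng):
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=1, sigma=0.1)
        base = fit_mle_noise(data, rng=rng)
        richer = FitResult(
            "sn_sigdep_alphabeta",
            SubjectParams(
                "sn_sigdep_alphabeta",
                np.vstack([truth.alpha] * 2),
                np.vstack([truth.beta] * 2),
            ),
            base.rss, base.n_obs, base.residuals,
            log_likelihood=base.log_likelihood,
        )
        # identical likelihood, k = 6 vs 12 -> AIC differs by exactly 12
        assert aic(richer) - aic(base) == pytest.approx(12.0, abs=1e-10)

    def test_nls_and_mle_paths_agree(self, rng):
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=2, sigma=0.1)
        f_nls = fit_nls(data, rng=np.random.default_rng(2))
        f_mle = fit_mle_noise(data, rng=np.random.default_rng(2))
        assert f_nls.aic == pytest.approx(f_mle.aic, abs=1e-6)

    def test_undefined_for_unconverged_fit(self):
        bad = FitResult("sn_original", None, np.inf, 0, np.array([]), converged=False)
        with pytest.raises(ValueError):
            aic(bad)


class TestCompareModels:
    def _cohort_fits(self, rng, n_subjects=4):
        fits = {"sn_original": [], "sn_sigdep_alphabeta": []}
        for _ in range(n_subjects):
            truth = sample_subject_params(PopulationSpec(), rng)
            data = _simulate(truth, rng, n_blocks=2, sigma=0.1)
            for v in fits:
                fits[v].append(fit_mle_noise(data, v, rng=rng, n_random_starts=1))
        return fits

    def test_identical_fits_give_zero_delta(self, rng):
        truth = sample_subject_params(PopulationSpec(), rng)
        data = _simulate(truth, rng, n_blocks=1, sigma=0.1)
        f = fit_mle_noise(data, rng=np.random.default_rng(2))
        summary, pairwise = compare_models({"a": [f, f], "b": [f, f]})
        assert pairwise.loc[0, "mean_delta_aic"] == 0.0
        assert pairwise.loc[0, "t"] == 0.0 and pairwise.loc[0, "p"] == 1.0

    def test_invariant_to_subject_order(self, rng):
        fits = self._cohort_fits(rng)
        perm = {v: [f[1], f[3], f[0], f[2]] for v, f in fits.items()}
        s1, _ = compare_models(fits)
        s2, _ = compare_models(perm)
        pd.testing.assert_frame_equal(s1, s2)

    def test_mismatched_subject_sets_rejected(self, rng):
        fits = self._cohort_fits(rng)
        fits["sn_original"].pop()
        with pytest.raises(ValueError):
            compare_models(fits)


class TestModelSelection:
    def test_aic_prefers_generating_sigdep_model(self):
        """Over 50 small cohorts generated with clearly distinct
        signal-class parameter sets, group-mean AIC picks the
        signal-dependent model > 80% of the time."""
        rng = np.random.default_rng(2024)
        truth = SubjectParams(
            "sn_sigdep_alphabeta",
            np.vstack([[3.5, 1.0, 0.6], [1.2, 0.4, 0.25]]),
            np.vstack([[1.7, 0.8, 0.6], [0.6, 0.3, 0.2]]),
        )
        wins = 0
        n_cohorts, n_subjects = 50, 3
        for _ in range(n_cohorts):
            aics = {"sn_original": [], "sn_sigdep_alphabeta": []}
            for _ in range(n_subjects):
                data = _simulate(truth, rng, n_blocks=2, sigma=0.05)
                for v in aics:
                    aics[v].append(
                        fit_mle_noise(data, v, rng=rng, n_random_starts=1).aic
                    )
            if np.mean(aics["sn_sigdep_alphabeta"]) < np.mean(aics["sn_original"]):
                wins += 1
        assert wins / n_cohorts > 0.8

    def test_aic_does_not_reward_spurious_flexibility(self, rng):
        """Data from the shared-parameter model: the richer
        signal-dependent model never wins by a meaningful AIC margin."""
        aics = {"sn_original": [], "sn_sigdep_alphabeta": []}
        for _ in range(8):
            truth = sample_subject_params(PopulationSpec(), rng)
            data = _simulate(truth, rng, n_blocks=2, sigma=0.1)
            for v in aics:
                aics[v].append(fit_mle_noise(data, v, rng=rng, n_random_starts=1).aic)
        delta = np.mean(aics["sn_original"]) - np.mean(aics["sn_sigdep_alphabeta"])
        assert delta < 2.0  # lowest or statistically tied


def test_fit_cohort_round_trips_csv_schema(rng, tmp_path):
    spec = PopulationSpec(n_subjects=2, log_sd=0.0)
    from regimeshift import simulate_population

    ds = simulate_population(spec, n_blocks=2, seed=11)
    fits = fit_cohort(ds.estimates, rng=rng)
    frame = fits_to_frame(fits)
    assert set(frame["subject_id"]) == {1, 2}
    assert len(frame) == 2 * 6
    # zero-dispersion cohort: both subjects share the true parameters
    for sid, f in fits.items():
        assert f.params.alpha == pytest.approx(ds.params_true[sid].alpha, abs=0.5)
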