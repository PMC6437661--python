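"""Generative noise model and Bayesian posterior stimulus decoding."""

import numpy as np
import pytest

from iemtools import (
    DegenerateDataError,
    NOISE_PRESETS,
    VoxelDataset,
    evenly_spaced_design,
    fit_noise_model,
    fit_weights,
    forward_channel_responses,
    log_likelihood,
    make_bimodal_transform,
    make_unimodal_basis,
    posterior_grid,
    simulate_dataset,
    simulate_population,
    summarize_posteriors,
    transform_basis,
)
from iemtools.bayes import _neg_log_likelihood_and_grad


@pytest.fixture(scope="module")
def fitted(design, unimodal_basis):
    population = simulate_population(seed=21)
    train = simulate_dataset(population, design, NOISE_PRESETS["low_noise"], seed=22)
    valid = simulate_dataset(
        population, design, NOISE_PRESETS["low_noise"], seed=23, role="validation"
    )
    fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
    noise = fit_noise_model(fit)
    return population, train, valid, fit, noise


class TestFitNoiseModel:
    def test_recovers_constant_tau_with_no_channel_noise(self, unimodal_basis):
        # synthetic residuals with known tau*, sigma_c* = 0, n = 2160
        design = evenly_spaced_design(8, 270)
        population = simulate_population(seed=0)
        pilot = simulate_dataset(population, design, 0.01, seed=1)
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), pilot)
        tau_true = 0.01
        rng = np.random.default_rng(42)
        r = forward_channel_responses(design, unimodal_basis).values
        data = VoxelDataset(
            responses=r @ fit.weights + rng.normal(0, tau_true, (2160, 100)),
            role="train", sigma=tau_true, seed=42, design=design,
        )
        noise = fit_noise_model(fit, data, design)
        assert np.abs(noise.tau - tau_true).max() / tau_true < 0.05
        assert noise.sigma_channel ** 2 <= 0.05 * np.mean(noise.tau ** 2)

    def test_recovers_injected_channel_noise(self, unimodal_basis):
        design = evenly_spaced_design(8, 270)
        population = simulate_population(seed=0)
        pilot = simulate_dataset(population, design, 0.01, seed=1)
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), pilot)
        tau_true, sc_true = 0.01, 0.05
        rng = np.random.default_rng(43)
        r = forward_channel_responses(design, unimodal_basis).values
        resid = rng.normal(0, sc_true, (2160, 8)) @ fit.weights + rng.normal(
            0, tau_true, (2160, 100)
        )
        data = VoxelDataset(
            responses=r @ fit.weights + resid, role="train", sigma=tau_true,
            seed=43, design=design,
        )
        noise = fit_noise_model(fit, data, design)
        assert abs(noise.sigma_channel - sc_true) / sc_true < 0.15

    def test_zero_residuals_raise_degenerate_error(self, design, unimodal_basis, noiseless_data):
        train, _ = noiseless_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        with pytest.raises(DegenerateDataError):
            fit_noise_model(fit)

    def test_analytic_gradient_matches_finite_differences(self, fitted):
        # directional central differences along random directions
        _, train, _, fit, _ = fitted
        r = forward_channel_responses(train.design, fit.basis).values
        z = train.responses - r @ fit.weights
        sz, gram, n = z.T @ z, fit.weights.T @ fit.weights, z.shape[0]
        x0 = np.concatenate([np.log((z ** 2).mean(axis=0)), [np.log(1e-5)]])
        _, grad = _neg_log_likelihood_and_grad(x0, sz, gram, n)
        rng = np.random.default_rng(0)
        eps = 1e-5
        for _ in range(5):
            direction = rng.normal(size=x0.size)
            direction /= np.linalg.norm(direction)
            f_plus = _neg_log_likelihood_and_grad(x0 + eps * direction, sz, gram, n)[0]
            f_minus = _neg_log_likelihood_and_grad(x0 - eps * direction, sz, gram, n)[0]
            numeric = (f_plus - f_minus) / (2 * eps)
            analytic = float(grad @ direction)
            assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-4)


class TestLogLikelihood:
    def test_at_the_mean_equals_normalisation_constant(self, fitted):
        _, _, _, fit, noise = fitted
        theta = 45.0
        mean = (fit.basis.evaluate([theta]) @ fit.weights)[0]
        ll = log_likelihood(mean, theta, fit, noise)
        v = mean.size
        expected = -0.5 * (v * np.log(2 * np.pi) + noise.log_det)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_factorised_density_matches_dense_oracle_small_v(self, unimodal_basis):
        # v = 10: compare the Cholesky route against an explicit inverse/det
        design = evenly_spaced_design(8, 27)
        population = simulate_population(v=10, seed=3)
        train = simulate_dataset(population, design, 0.01, seed=4)
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        noise = fit_noise_model(fit)
        row = train.responses[5]
        for theta in (0.0, 10.0, 67.5):
            mean = (unimodal_basis.evaluate([theta]) @ fit.weights)[0]
            resid = row - mean
            omega_inv = np.linalg.inv(noise.omega)
            dense = -0.5 * (
                resid @ omega_inv @ resid
                + np.log(np.linalg.det(noise.omega))
                + 10 * np.log(2 * np.pi)
            )
            assert log_likelihood(row, theta, fit, noise) == pytest.approx(dense, abs=1e-8)

    def test_axial_periodicity(self, fitted):
        _, _, valid, fit, noise = fitted
        row = valid.responses[0]
        assert log_likelihood(row, 30.0, fit, noise) == pytest.approx(
            log_likelihood(row, 210.0, fit, noise), abs=1e-10
        )


class TestPosteriorGrid:
    def test_rows_are_normalised_probabilities(self, fitted):
        _, _, valid, fit, noise = fitted
        posteriors = posterior_grid(valid, fit, noise, grid_step=1.0)
        assert posteriors.probabilities.shape == (216, 180)
        assert (posteriors.probabilities >= 0).all()
        assert np.abs(posteriors.probabilities.sum(axis=1) - 1.0).max() < 1e-12

    def test_zero_weight_fit_gives_uniform_posterior(self, fitted):
        _, _, valid, fit, noise = fitted
        zero_fit = type(fit)(
            weights=np.zeros_like(fit.weights), r2_train=0.0,
            basis=fit.basis, design=fit.design, training=fit.training,
        )
        posteriors = posterior_grid(valid, zero_fit, noise, grid_step=1.0)
        assert np.allclose(posteriors.probabilities, 1.0 / 180.0, atol=1e-12)

    def test_posterior_is_basis_independent(self, design, unimodal_basis, bimodal_basis):
        population = simulate_population(seed=31)
        train = simulate_dataset(population, design, NOISE_PRESETS["low_noise"], seed=32)
        valid = simulate_dataset(
            population, design, NOISE_PRESETS["low_noise"], seed=33, role="validation"
        )
        maps = []
        for basis in (unimodal_basis, bimodal_basis):
            fit = fit_weights(forward_channel_responses(design, basis), train)
            noise = fit_noise_model(fit)
            maps.append(posterior_grid(valid, fit, noise, grid_step=0.5).probabilities)
        assert np.abs(maps[0] - maps[1]).max() < 1e-6

    def test_invalid_grid_step_rejected(self, fitted):
        _, _, valid, fit, noise = fitted
        with pytest.raises(Exception):
            posterior_grid(valid, fit, noise, grid_step=7.0)


class TestSummarizePosteriors:
    def test_aligned_average_unimodal_at_truth_low_noise(self, fitted):
        _, _, valid, fit, noise = fitted
        summary = summarize_posteriors(posterior_grid(valid, fit, noise, grid_step=0.5))
        assert summary.n_local_maxima == 1
        assert abs(summary.peak_offset_deg) <= 0.5  # at truth, within one grid bin

    def test_fwhm_grows_with_noise_on_matched_seeds(self, design, unimodal_basis):
        population = simulate_population(seed=41)
        widths = {}
        for preset in ("low_noise", "high_noise"):
            sigma = NOISE_PRESETS[preset]
            train = simulate_dataset(population, design, sigma, seed=42)
            valid = simulate_dataset(population, design, sigma, seed=43, role="validation")
            fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
            noise = fit_noise_model(fit)
            summary = summarize_posteriors(posterior_grid(valid, fit, noise, grid_step=0.5))
            widths[preset] = summary.fwhm_deg
        assert widths["high_noise"] > widths["low_noise"]

    def test_map_error_concentrates_at_vanishing_noise(self, design, unimodal_basis):
        # as sigma -> 0 the MAP estimate collapses onto the true orientation
        population = simulate_population(seed=51)
        train = simulate_dataset(population, design, 0.002, seed=52)
        valid = simulate_dataset(population, design, 0.002, seed=53, role="validation")
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        noise = fit_noise_model(fit)
        summary = summarize_posteriors(posterior_grid(valid, fit, noise, grid_step=0.5))
        assert summary.per_trial["circular_error_deg"].median() <= 0.5

    def test_single_symmetric_trial(self, fitted):
        from iemtools.bayes import PosteriorMap

        grid = np.arange(0.0, 180.0, 0.5)
        probs = np.exp(-0.5 * (((grid - 45.0 + 90) % 180 - 90) / 2.0) ** 2)
        probs /= probs.sum()
        posteriors = PosteriorMap(
            grid=grid, probabilities=probs[None, :], true_orientations=np.array([45.0])
        )
        summary = summarize_posteriors(posteriors)
        assert summary.per_trial["circular_error_deg"].iloc[0] == 0.0
        assert summary.n_local_maxima == 1
        assert summary.peak_offset_deg == 0.0
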