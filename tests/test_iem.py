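"""Encoding-model fitting, prediction, inversion, and shift-averaging."""

import numpy as np
import pytest

from iemtools import (
    AlignmentError,
    ChannelResponses,
    InvalidParameterError,
    SingularFitError,
    StimulusDesign,
    VoxelDataset,
    evenly_spaced_design,
    fit_weights,
    forward_channel_responses,
    invert_model,
    make_bimodal_transform,
    make_unimodal_basis,
    predict_bold,
    shift_average,
    simulate_dataset,
    transform_basis,
    variance_explained,
)
from iemtools.basis import evaluate_basis
from iemtools.metrics import CircularCurve, local_maxima, peak_separation


class TestForwardChannelResponses:
    def test_rows_are_basis_rows_for_presented_orientation(self, unimodal_basis, design):
        r = forward_channel_responses(design, unimodal_basis)
        c = evaluate_basis(unimodal_basis, design)
        assert np.array_equal(r.values, c[design.trial_indices])

    def test_forward_transform_identity(self, unimodal_basis, design):
        transform = make_bimodal_transform()
        r1 = forward_channel_responses(design, unimodal_basis)
        r2 = forward_channel_responses(design, transform_basis(unimodal_basis, transform))
        assert np.abs(r2.values - r1.values @ transform.matrix).max() < 1e-12


class TestFitWeights:
    def test_exact_interpolation_at_zero_noise(self, unimodal_basis, design):
        # B generated as R @ W for a known W is recovered exactly
        r = forward_channel_responses(design, unimodal_basis)
        w_true = np.random.default_rng(0).normal(size=(8, 5))
        data = VoxelDataset(
            responses=r.values @ w_true, role="train", sigma=0.0, seed=None, design=design
        )
        fit = fit_weights(r, data)
        assert np.allclose(fit.weights, w_true, atol=1e-9)
        assert fit.r2_train == pytest.approx(1.0, abs=1e-10)

    def test_normal_equations_by_hand(self):
        # R = [[1,0],[0,2]], B = [[2,3],[4,6]] -> W = (R'R)^-1 R'B = [[2,3],[2,3]]
        design = evenly_spaced_design(2, 1)
        basis = make_unimodal_basis(2)
        r = ChannelResponses(
            values=np.array([[1.0, 0.0], [0.0, 2.0]]), role="forward",
            basis=basis, design=design,
        )
        data = VoxelDataset(
            responses=np.array([[2.0, 3.0], [4.0, 6.0]]), role="train",
            sigma=0.0, seed=None, design=design,
        )
        assert np.allclose(fit_weights(r, data).weights, [[2.0, 3.0], [2.0, 3.0]])

    def test_full_rank_default_configuration(self, unimodal_basis, design, noisy_data):
        train, _ = noisy_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        assert fit.weights.shape == (8, 100)

    def test_rank_deficient_design_rejected(self, unimodal_basis, population):
        # 7 distinct orientations cannot identify 8 channels: rank(SC) <= 7
        full = evenly_spaced_design(8, 27)
        keep = full.trial_orientations != full.orientations[0]
        seven = StimulusDesign(
            orientations=full.orientations[1:],
            trial_orientations=full.trial_orientations[keep],
        )
        data = simulate_dataset(population, seven, 0.01, seed=1)
        with pytest.raises(SingularFitError, match="rank 7"):
            fit_weights(forward_channel_responses(seven, unimodal_basis), data)


class TestPredictBold:
    def test_reproduces_noiseless_training_data(self, unimodal_basis, design, noiseless_data):
        train, _ = noiseless_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        assert np.allclose(predict_bold(fit, design), train.responses, atol=1e-9)

    def test_zero_weights_predict_zero(self, unimodal_basis, design, noiseless_data):
        train, _ = noiseless_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        zero_fit = type(fit)(
            weights=np.zeros_like(fit.weights), r2_train=0.0,
            basis=fit.basis, design=fit.design, training=fit.training,
        )
        assert np.array_equal(predict_bold(zero_fit, design), np.zeros((216, 100)))


class TestInvertModel:
    def test_zero_noise_recovers_forward_responses(self, unimodal_basis, design, noiseless_data):
        train, valid = noiseless_data
        r = forward_channel_responses(design, unimodal_basis)
        fit = fit_weights(r, train)
        recon = invert_model(fit, valid)
        assert np.allclose(recon.values, r.values, atol=1e-8)

    def test_matches_per_trial_brute_force_least_squares(
        self, unimodal_basis, design, noisy_data
    ):
        # oracle: explicit normal equations, solved per trial with a dense inverse
        train, valid = noisy_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        recon = invert_model(fit, valid)
        w = fit.weights
        gram_inv = np.linalg.inv(w @ w.T)
        for t in range(0, valid.n_trials, 17):
            oracle = valid.responses[t] @ w.T @ gram_inv
            assert np.abs(recon.values[t] - oracle).max() < 1e-10

    def test_zero_validation_gives_zero_reconstruction(
        self, unimodal_basis, design, noisy_data
    ):
        train, _ = noisy_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        zeros = VoxelDataset(
            responses=np.zeros((216, 100)), role="validation", sigma=0.0,
            seed=None, design=design,
        )
        assert np.abs(invert_model(fit, zeros).values).max() < 1e-12


class TestShiftAverage:
    def test_zero_noise_unimodal_crf_is_basis_profile(
        self, unimodal_basis, design, noiseless_data
    ):
        train, valid = noiseless_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        crf = shift_average(invert_model(fit, valid))
        profile = unimodal_basis.evaluate(crf.offsets)[:, 0]  # center-0 channel
        assert np.abs(crf.mean - profile).max() < 1e-6
        assert crf.mean[list(crf.offsets).index(0.0)] == pytest.approx(1.0, abs=1e-6)

    def test_zero_noise_bimodal_crf_has_two_peaks_67_5_apart(
        self, bimodal_basis, design, noiseless_data
    ):
        train, valid = noiseless_data
        fit = fit_weights(forward_channel_responses(design, bimodal_basis), train)
        crf = shift_average(invert_model(fit, valid))
        curve = CircularCurve(offsets=crf.offsets, values=crf.mean)
        peaks = local_maxima(curve)
        assert len(peaks) == 2
        assert {crf.offsets[p] for p in peaks} == {0.0, 67.5}
        assert peak_separation(curve) == pytest.approx(67.5)

    def test_single_trial_mean_is_that_trial(self, unimodal_basis):
        design = StimulusDesign(orientations=[22.5], trial_orientations=[22.5])
        values = np.arange(8.0)[None, :]
        recon = ChannelResponses(
            values=values, role="reconstructed", basis=unimodal_basis, design=design
        )
        crf = shift_average(recon)
        assert np.array_equal(np.sort(crf.mean), np.arange(8.0))
        assert np.array_equal(crf.sem, np.zeros(8))
        assert crf.n_trials == 1

    def test_off_center_orientation_rejected(self, unimodal_basis):
        design = StimulusDesign(orientations=[10.0], trial_orientations=[10.0])
        recon = ChannelResponses(
            values=np.zeros((1, 8)), role="reconstructed",
            basis=unimodal_basis, design=design,
        )
        with pytest.raises(AlignmentError):
            shift_average(recon)


class TestVarianceExplained:
    def test_perfect_on_noiseless_training_data(self, unimodal_basis, design, noiseless_data):
        train, _ = noiseless_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        assert variance_explained(fit, train) == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_formula_for_zero_weight_fit(
        self, unimodal_basis, design, noisy_data
    ):
        train, _ = noisy_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        zero_fit = type(fit)(
            weights=np.zeros_like(fit.weights), r2_train=0.0,
            basis=fit.basis, design=fit.design, training=fit.training,
        )
        b = train.responses
        expected = 1.0 - (b ** 2).sum() / ((b - b.mean()) ** 2).sum()
        assert variance_explained(zero_fit, train) == pytest.approx(expected, abs=1e-12)
        assert variance_explained(zero_fit, train) <= 0.0

    def test_validation_r2_non_decreasing_as_noise_falls(self, population, design, unimodal_basis):
        r2s = []
        for sigma in (0.032, 0.008, 0.0):
            train = simulate_dataset(population, design, sigma, seed=31, role="train")
            valid = simulate_dataset(population, design, sigma, seed=32, role="validation")
            fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
            r2s.append(variance_explained(fit, valid))
        assert r2s[0] < r2s[1] < r2s[2] <= 1.0 + 1e-12

    def test_per_voxel_variant_matches_explicit_formula(self, unimodal_basis, design, noisy_data):
        # mean over voxels of 1 - SSres_v / SStot_v (SStot about each voxel's mean);
        # differs from the pooled ratio because weakly tuned voxels pull it down
        train, valid = noisy_data
        fit = fit_weights(forward_channel_responses(design, unimodal_basis), train)
        pred = predict_bold(fit, design)
        b = valid.responses
        expected = np.mean(
            1.0
            - ((b - pred) ** 2).sum(axis=0)
            / ((b - b.mean(axis=0)) ** 2).sum(axis=0)
        )
        per_voxel = variance_explained(fit, valid, per_voxel=True)
        assert per_voxel == pytest.approx(expected, abs=1e-12)
        assert per_voxel <= variance_explained(fit, valid)
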