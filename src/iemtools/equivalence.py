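"""Executable identity checks for transform-equivalent encoding models.

Two channel bases related by an invertible transform P (C₂ = C₁P) produce
encoding models that are mathematically interchangeable.  Concretely:

* weight identity:            Ŵ₂ = P⁻¹ Ŵ₁
* left-out prediction:        B̂₂,LO = B̂₁,LO  (even at untrained orientations)
* reconstruction identity:    R̂₂ = R̂₁ P
* variance equality:          r²₁ = r²₂

These hold at any noise level; numerically the discrepancy scales with the
transform's condition number times machine epsilon, so for cond(P) < 10³ a
relative tolerance of 1e-8 is comfortable.  Each check returns an
:class:`EquivalenceReport` with the relative Frobenius discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .basis import (
    ChannelTransform,
    StimulusDesign,
    evenly_spaced_design,
    make_bimodal_transform,
    make_random_transform,
    make_unimodal_basis,
    transform_basis,
)
from .errors import InvalidParameterError
from .iem import (
    ChannelResponses,
    EncodingFit,
    fit_weights,
    forward_channel_responses,
    invert_model,
    predict_bold,
    variance_explained,
)
from .simulate import NOISE_PRESETS, simulate_dataset, simulate_population

__all__ = [
    "EquivalenceReport",
    "check_weight_identity",
    "check_reconstruction_identity",
    "check_leftout_prediction",
    "check_variance_equality",
    "run_equivalence_suite",
]

DEFAULT_TOLERANCE = 1e-8
_ABS_FALLBACK = 1e-12


@dataclass(frozen=True)
class EquivalenceReport:
    """Outcome of one identity check on one configuration."""

    name: str
    discrepancy: float
    tolerance: float
    passed: bool
    fingerprint: dict = field(default_factory=dict)

    def as_record(self) -> dict:
        rec = {
            "identity": self.name,
            "discrepancy": self.discrepancy,
            "tolerance": self.tolerance,
            "passed": self.passed,
        }
        rec.update(self.fingerprint)
        return rec


def relative_discrepancy(delta: np.ndarray, reference: np.ndarray) -> float:
    """Relative Frobenius discrepancy ‖Δ‖_F / ‖ref‖_F.

    Falls back to the absolute norm when the reference norm is below 1e-12,
    so an identically zero reference still yields a meaningful number.
    """
    ref_norm = float(np.linalg.norm(reference))
    delta_norm = float(np.linalg.norm(delta))
    if ref_norm < _ABS_FALLBACK:
        return delta_norm
    return delta_norm / ref_norm


def _report(name, discrepancy, tolerance, fingerprint) -> EquivalenceReport:
    return EquivalenceReport(
        name=name,
        discrepancy=float(discrepancy),
        tolerance=float(tolerance),
        passed=bool(discrepancy <= tolerance),
        fingerprint=dict(fingerprint or {}),
    )


def check_weight_identity(
    fit_1: EncodingFit,
    fit_2: EncodingFit,
    transform: ChannelTransform,
    tolerance: float = DEFAULT_TOLERANCE,
    fingerprint: Optional[dict] = None,
) -> EquivalenceReport:
    """Check Ŵ₂ = P⁻¹ Ŵ₁ for two fits of the same training data."""
    if fit_1.training is not fit_2.training and not np.array_equal(
        fit_1.training.responses, fit_2.training.responses
    ):
        raise InvalidParameterError("weight identity requires fits on the same training data")
    expected = np.linalg.solve(transform.matrix, fit_1.weights)
    disc = relative_discrepancy(fit_2.weights - expected, fit_1.weights)
    return _report("weight_identity", disc, tolerance, fingerprint)


def check_reconstruction_identity(
    recon_1: ChannelResponses,
    recon_2: ChannelResponses,
    transform: ChannelTransform,
    tolerance: float = DEFAULT_TOLERANCE,
    fingerprint: Optional[dict] = None,
) -> EquivalenceReport:
    """Check R̂₂ = R̂₁ P for reconstructions from the same validation data."""
    disc = relative_discrepancy(
        recon_2.values - recon_1.values @ transform.matrix, recon_1.values
    )
    return _report("reconstruction_identity", disc, tolerance, fingerprint)


def check_leftout_prediction(
    fit_1: EncodingFit,
    fit_2: EncodingFit,
    leftout_design: StimulusDesign,
    tolerance: float = DEFAULT_TOLERANCE,
    fingerprint: Optional[dict] = None,
) -> EquivalenceReport:
    """Check B̂₂,LO = B̂₁,LO at orientations excluded from both trainings."""
    for fit in (fit_1, fit_2):
        if np.isin(leftout_design.orientations, fit.design.orientations).any():
            raise InvalidParameterError(
                "left-out orientations must be absent from both training designs"
            )
    pred_1 = predict_bold(fit_1, leftout_design)
    pred_2 = predict_bold(fit_2, leftout_design)
    disc = relative_discrepancy(pred_2 - pred_1, pred_1)
    return _report("leftout_prediction", disc, tolerance, fingerprint)


def check_variance_equality(
    fit_1: EncodingFit,
    fit_2: EncodingFit,
    dataset,
    tolerance: float = 1e-10,
    fingerprint: Optional[dict] = None,
) -> EquivalenceReport:
    """Check that both fits explain exactly the same variance of a dataset."""
    r2_1 = variance_explained(fit_1, dataset)
    r2_2 = variance_explained(fit_2, dataset)
    disc = abs(r2_1 - r2_2)
    return _report("variance_equality", disc, tolerance, fingerprint)


def _make_transform(kind: str, k: int, seed: int) -> ChannelTransform:
    if kind == "bimodal":
        return make_bimodal_transform(k=k)
    if kind == "random":
        return make_random_transform(k=k, seed=seed)
    raise InvalidParameterError(f"unknown transform kind {kind!r}")


def run_equivalence_suite(
    seeds: Iterable[int] = (0, 1, 2, 3, 4),
    sigmas: Optional[dict[str, float]] = None,
    transform_kinds: Iterable[str] = ("bimodal", "random"),
    k: int = 8,
    v: int = 100,
    m: int = 180,
    h: float = 40.0,
    n_orientations: int = 8,
    repeats: int = 27,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[EquivalenceReport]:
    """Run all identity checks over a (seed × noise × transform) grid.

    For each cell: simulate a population plus train/validation datasets, fit
    the unimodal model and the transformed model on the same training data,
    and evaluate the four identities.  The left-out check trains both models
    on a denser design (2k orientations) with one orientation removed and
    predicts the removed one, so the training channel-response matrix stays
    full rank.  Empty ``seeds`` or ``sigmas`` yield an empty report list.
    """
    if sigmas is None:
        sigmas = dict(NOISE_PRESETS)
    reports: list[EquivalenceReport] = []
    for seed in seeds:
        population = simulate_population(v=v, m=m, h=h, seed=seed)
        design = evenly_spaced_design(n_orientations, repeats)
        basis_1 = make_unimodal_basis(k=k)
        r1 = forward_channel_responses(design, basis_1)
        # dense design for the left-out check: 2k orientations, drop one
        dense = evenly_spaced_design(2 * k, max(1, repeats // 2))
        dropped = dense.orientations[1]
        keep = dense.trial_orientations != dropped
        train_lo = StimulusDesign(
            orientations=np.delete(dense.orientations, 1),
            trial_orientations=dense.trial_orientations[keep],
        )
        leftout = StimulusDesign(
            orientations=np.array([dropped]),
            trial_orientations=np.full(4, dropped),
        )
        for preset, sigma in sigmas.items():
            train = simulate_dataset(population, design, sigma, seed=10_000 + seed, role="train")
            valid = simulate_dataset(
                population, design, sigma, seed=20_000 + seed, role="validation"
            )
            train_lo_ds = simulate_dataset(
                population, train_lo, sigma, seed=30_000 + seed, role="train"
            )
            fit_1 = fit_weights(r1, train)
            fit_1_lo = fit_weights(forward_channel_responses(train_lo, basis_1), train_lo_ds)
            recon_1 = invert_model(fit_1, valid)
            for kind in transform_kinds:
                transform = _make_transform(kind, k, seed=40_000 + seed)
                basis_2 = transform_basis(basis_1, transform)
                fp = {"seed": seed, "noise_preset": preset, "sigma": sigma, "transform": kind}
                fit_2 = fit_weights(forward_channel_responses(design, basis_2), train)
                fit_2_lo = fit_weights(
                    forward_channel_responses(train_lo, basis_2), train_lo_ds
                )
                recon_2 = invert_model(fit_2, valid)
                reports.append(check_weight_identity(fit_1, fit_2, transform, tolerance, fp))
                reports.append(
                    check_reconstruction_identity(recon_1, recon_2, transform, tolerance, fp)
                )
                reports.append(
                    check_leftout_prediction(fit_1_lo, fit_2_lo, leftout, tolerance, fp)
                )
                reports.append(check_variance_equality(fit_1, fit_2, valid, 1e-10, fp))
    return reports
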