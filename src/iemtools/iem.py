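"""Forward encoding model fitting and inversion.

The forward model writes the trial-by-voxel response matrix as
B = R W + η, where R = S C are the channel responses evoked by the one-hot
stimulus matrix S under channel basis C, and W is a k×v weight matrix.
Weights are estimated by ordinary least squares on a training set,

    Ŵ = (RᵀR)⁻¹ Rᵀ B_T,

and the model is inverted on held-out validation data by projecting each
trial's voxel vector back into channel space,

    R̂ = B_V Ŵᵀ (Ŵ Ŵᵀ)⁻¹.

Internally both solves use numerically stabilised factorisations; the
explicit normal-equations expressions above are exactly what they compute
(the test suite verifies this against brute-force least squares).

Reconstructed channel responses are summarised the way the field plots them:
each trial's k-vector is circularly shifted so the channel preferring the
presented orientation lands at offset 0, then averaged across trials
("shift-and-average").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .basis import ChannelBasis, StimulusDesign, evaluate_basis
from .errors import (
    AlignmentError,
    InvalidParameterError,
    InversionError,
    SingularFitError,
)
from .simulate import VoxelDataset

__all__ = [
    "ChannelResponses",
    "EncodingFit",
    "AlignedCRF",
    "forward_channel_responses",
    "fit_weights",
    "predict_bold",
    "invert_model",
    "shift_average",
    "variance_explained",
]


@dataclass(frozen=True)
class ChannelResponses:
    """Trial-by-channel response matrix, either forward (R = S C) or reconstructed (R̂)."""

    values: np.ndarray  # (n, k)
    role: str  # "forward" | "reconstructed"
    basis: ChannelBasis
    design: StimulusDesign

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if self.role not in ("forward", "reconstructed"):
            raise InvalidParameterError(f"unknown role {self.role!r}")
        if values.shape[0] != self.design.n_trials:
            raise InvalidParameterError("row count does not match design trials")
        if values.shape[1] != self.basis.k:
            raise InvalidParameterError("column count does not match basis channels")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class EncodingFit:
    """Least-squares encoding-model fit: weights Ŵ plus training diagnostics."""

    weights: np.ndarray  # (k, v)
    r2_train: float
    basis: ChannelBasis
    design: StimulusDesign
    training: VoxelDataset

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class AlignedCRF:
    """Shift-and-averaged channel response function.

    ``offsets`` are the k channel positions relative to the presented
    orientation (spacing 180/k, offset 0 included); ``mean`` and ``sem`` are
    across the n aligned trials.
    """

    offsets: np.ndarray  # (k,) degrees, centered at 0
    mean: np.ndarray  # (k,)
    sem: np.ndarray  # (k,)
    n_trials: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset_deg": self.offsets, "mean": self.mean, "sem": self.sem,
             "n_trials": self.n_trials}
        )


def forward_channel_responses(design: StimulusDesign, basis: ChannelBasis) -> ChannelResponses:
    """Forward channel responses R = S C for every trial."""
    c = evaluate_basis(basis, design)
    r = design.design_matrix @ c
    return ChannelResponses(values=r, role="forward", basis=basis, design=design)


def fit_weights(channel_responses: ChannelResponses, training: VoxelDataset) -> EncodingFit:
    """Ordinary least-squares weights Ŵ = (RᵀR)⁻¹RᵀB_T.

    Raises :class:`SingularFitError` if R is rank deficient (fewer effective
    channels than k), reporting the rank.
    """
    r = channel_responses.values
    b = training.responses
    if r.shape[0] != b.shape[0]:
        raise InvalidParameterError(
            f"channel responses have {r.shape[0]} trials but training data has {b.shape[0]}"
        )
    k = r.shape[1]
    rank = int(np.linalg.matrix_rank(r))
    if rank < k:
        raise SingularFitError(
            f"channel response matrix is rank deficient: rank {rank} < k = {k}"
        )
    weights, *_ = np.linalg.lstsq(r, b, rcond=None)
    resid = b - r @ weights
    ss_tot = float(((b - b.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return EncodingFit(
        weights=weights,
        r2_train=r2,
        basis=channel_responses.basis,
        design=channel_responses.design,
        training=training,
    )


def predict_bold(fit: EncodingFit, design: StimulusDesign) -> np.ndarray:
    """Predicted responses B̂ = S C Ŵ at the given design's orientations.

    The design may contain orientations never seen during training; C is
    re-evaluated at the design's stimulus values.
    """
    c = evaluate_basis(fit.basis, design)
    return design.design_matrix @ c @ fit.weights


def invert_model(fit: EncodingFit, validation: VoxelDataset) -> ChannelResponses:
    """Inverted-model channel responses R̂ = B_V Ŵᵀ (Ŵ Ŵᵀ)⁻¹.

    Each row of R̂ is the least-squares solution of b_t ≈ r Ŵ for that trial.
    Raises :class:`InversionError` when Ŵ Ŵᵀ is numerically singular.
    """
    w = fit.weights
    if validation.n_voxels != fit.n_voxels:
        raise InvalidParameterError("validation voxel count does not match fit")
    cond = float(np.linalg.cond(w.T))
    if not np.isfinite(cond) or cond > 1e12:
        raise InversionError(
            f"weight Gram matrix Ŵ Ŵᵀ is singular (cond(Ŵ) = {cond:.3g})"
        )
    # each row of R̂ solves min_r ‖b_t − r Ŵ‖, identical to B_V Ŵᵀ(ŴŴᵀ)⁻¹ but
    # solved by SVD on Ŵᵀ, which avoids squaring the conditioning in the Gram
    rhat, *_ = np.linalg.lstsq(w.T, validation.responses.T, rcond=None)
    rhat = rhat.T
    return ChannelResponses(
        values=rhat, role="reconstructed", basis=fit.basis, design=validation.design
    )


def shift_average(
    responses: ChannelResponses,
    design: Optional[StimulusDesign] = None,
    basis: Optional[ChannelBasis] = None,
    atol: float = 1e-9,
) -> AlignedCRF:
    """Circularly align each trial's channel vector to its presented orientation.

    Every presented orientation must coincide (within ``atol`` degrees) with a
    channel center; the channel preferring the presented orientation is placed
    at offset 0 and the remaining channels at multiples of the channel spacing
    either side.  Off-center designs raise :class:`AlignmentError` — they are
    not interpolated.
    """
    design = design if design is not None else responses.design
    basis = basis if basis is not None else responses.basis
    k = basis.k
    spacing = basis.spacing
    ratio = design.trial_orientations / spacing
    center_idx = np.rint(ratio).astype(int)
    if not np.allclose(ratio, center_idx, rtol=0, atol=atol / spacing):
        off = design.trial_orientations[~np.isclose(ratio, center_idx, rtol=0, atol=atol / spacing)]
        raise AlignmentError(
            f"presented orientations {np.unique(off)} do not coincide with channel centers"
        )
    center_idx %= k
    n = design.n_trials
    half = k // 2
    offsets = (np.arange(k) - half) * spacing
    cols = (center_idx[:, None] + np.arange(k)[None, :] - half) % k
    aligned = responses.values[np.arange(n)[:, None], cols]
    mean = aligned.mean(axis=0)
    if n > 1:
        sem = aligned.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros(k)
    return AlignedCRF(offsets=offsets, mean=mean, sem=sem, n_trials=n)


def variance_explained(
    fit: EncodingFit,
    dataset: VoxelDataset,
    design: Optional[StimulusDesign] = None,
    per_voxel: bool = False,
) -> float:
    """Variance explained r² = 1 − SS_res/SS_tot of the fit on a dataset.

    By default both sums pool over all trials and voxels with SS_tot taken
    about the grand mean of the dataset.  With ``per_voxel=True`` an r² is
    computed per voxel (SS_tot about that voxel's mean) and averaged.
    """
    design = design if design is not None else dataset.design
    pred = predict_bold(fit, design)
    b = dataset.responses
    resid = b - pred
    if per_voxel:
        ss_res = (resid ** 2).sum(axis=0)
        ss_tot = ((b - b.mean(axis=0, keepdims=True)) ** 2).sum(axis=0)
        return float(np.mean(1.0 - ss_res / ss_tot))
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((b - b.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def export_aligned_crf(
    crf: AlignedCRF, path, basis_kind: str = "", noise_preset: str = ""
) -> None:
    """Write an aligned CRF as delimited text.

    Columns: basis_kind, noise_preset, offset_deg, mean, sem, n_trials.
    """
    frame = crf.as_frame()
    frame.insert(0, "noise_preset", noise_preset)
    frame.insert(0, "basis_kind", basis_kind)
    frame.to_csv(path, index=False)
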