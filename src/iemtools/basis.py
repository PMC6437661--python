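"""Channel basis functions, stimulus designs, and invertible basis transforms.

Orientation is an axial variable: angles live on [0, 180) degrees and all
tuning functions have period 180°.  The canonical ("unimodal") channel basis
is a half-wave rectified cosine in doubled-angle space raised to an integer
exponent,

    f_j(θ) = max(0, cos(2 (θ − φ_j) π/180))**p,

with k channel centers φ_j evenly spaced on [0, 180).  Any invertible k×k
matrix P defines an equally valid basis C₂ = C₁ P spanning the same subspace;
this module constructs two families of such transforms — a circulant
"bimodal" transform P = I + g·Πᵐ (Π the one-step cyclic channel permutation)
and a random Gaussian transform accepted only below a condition-number
ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import (
    ConditioningError,
    InvalidParameterError,
    SingularTransformError,
)

PERIOD_DEG = 180.0

__all__ = [
    "PERIOD_DEG",
    "ChannelBasis",
    "ChannelTransform",
    "StimulusDesign",
    "make_unimodal_basis",
    "evaluate_basis",
    "make_bimodal_transform",
    "make_random_transform",
    "transform_basis",
    "evenly_spaced_design",
    "basis_to_config",
    "basis_from_config",
    "export_basis_grid",
]


@dataclass(frozen=True)
class ChannelTransform:
    """An invertible k×k linear map between equivalent channel bases."""

    matrix: np.ndarray
    kind: str  # "bimodal" | "random" | "custom"
    condition_number: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidParameterError("transform matrix must be square")
        object.__setattr__(self, "matrix", m)

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        """Right-multiply row vectors (or a matrix of rows) by P."""
        return np.asarray(vectors, dtype=float) @ self.matrix

    def unapply(self, vectors: np.ndarray) -> np.ndarray:
        """Right-multiply row vectors by P⁻¹ (inverse mapping)."""
        return np.asarray(vectors, dtype=float) @ self.inverse


@dataclass(frozen=True)
class ChannelBasis:
    """A set of k channel tuning functions over orientation.

    ``kind`` is "unimodal" for the canonical rectified-cosine basis and
    "transformed" for a basis obtained as C₂ = C₁ P; transformed bases keep a
    reference to their parent transform so reconstructions can be mapped back.
    """

    k: int
    exponent: int
    centers: np.ndarray
    kind: str = "unimodal"
    transform: Optional[ChannelTransform] = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InvalidParameterError(f"need at least 2 channels, got k={self.k}")
        if self.exponent < 1:
            raise InvalidParameterError(f"exponent must be >= 1, got {self.exponent}")
        if self.kind not in ("unimodal", "transformed"):
            raise InvalidParameterError(f"unknown basis kind {self.kind!r}")
        if (self.kind == "transformed") != (self.transform is not None):
            raise InvalidParameterError(
                "transformed bases require a parent transform; unimodal bases forbid one"
            )
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))

    @property
    def spacing(self) -> float:
        return PERIOD_DEG / self.k

    def evaluate(self, angles_deg: Sequence[float] | np.ndarray) -> np.ndarray:
        """Evaluate all k channel functions at the given angles.

        Returns an (n_angles, k) matrix; row i holds the k channel values at
        angle i.  Evaluation is 180°-periodic.
        """
        angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
        if angles.size == 0:
            raise InvalidParameterError("cannot evaluate basis at an empty angle set")
        delta = angles[:, None] - self.centers[None, :]
        values = np.maximum(0.0, np.cos(2.0 * np.deg2rad(delta))) ** self.exponent
        if self.kind == "transformed":
            values = values @ self.transform.matrix
        return values


@dataclass(frozen=True)
class StimulusDesign:
    """Trial sequence of orientation stimuli with its one-hot design matrix.

    ``orientations`` are the s distinct stimulus values (sorted, degrees in
    [0, 180)); ``trial_orientations`` gives the presented value on each of the
    n trials.  The design matrix S is n×s with a single 1 per row.
    """

    orientations: np.ndarray
    trial_orientations: np.ndarray
    repeats: int = field(default=0)

    def __post_init__(self) -> None:
        oris = np.asarray(self.orientations, dtype=float)
        trials = np.asarray(self.trial_orientations, dtype=float)
        if oris.size == 0 or trials.size == 0:
            raise InvalidParameterError("design needs at least one orientation and one trial")
        if np.any(oris < 0) or np.any(oris >= PERIOD_DEG):
            raise InvalidParameterError("orientations must lie in [0, 180)")
        if np.unique(oris).size != oris.size or np.any(np.diff(oris) <= 0):
            raise InvalidParameterError("orientations must be distinct and sorted")
        if not np.isin(trials, oris).all():
            raise InvalidParameterError("every trial orientation must be a design orientation")
        object.__setattr__(self, "orientations", oris)
        object.__setattr__(self, "trial_orientations", trials)

    @property
    def n_trials(self) -> int:
        return self.trial_orientations.size

    @property
    def n_stimuli(self) -> int:
        return self.orientations.size

    @property
    def trial_indices(self) -> np.ndarray:
        """Index of each trial's orientation into the distinct-orientation list."""
        return np.searchsorted(self.orientations, self.trial_orientations)

    @property
    def design_matrix(self) -> np.ndarray:
        """The n×s one-hot stimulus matrix S."""
        s = np.zeros((self.n_trials, self.n_stimuli))
        s[np.arange(self.n_trials), self.trial_indices] = 1.0
        return s


def evenly_spaced_design(n_orientations: int = 8, repeats: int = 27) -> StimulusDesign:
    """Build the default design: evenly spaced orientations, each shown `repeats` times.

    The default (8 orientations × 27 repeats, n = 216) matches the simulated
    experiment the package reproduces.
    """
    if n_orientations < 1 or repeats < 1:
        raise InvalidParameterError("n_orientations and repeats must be positive")
    oris = np.arange(n_orientations) * PERIOD_DEG / n_orientations
    trials = np.tile(oris, repeats)
    return StimulusDesign(orientations=oris, trial_orientations=trials, repeats=repeats)


def make_unimodal_basis(k: int = 8, p: Optional[int] = None) -> ChannelBasis:
    """Canonical rectified-cosine channel basis with k evenly spaced centers.

    The exponent defaults to k − 1, the usual choice that keeps the basis
    functions narrow enough to be linearly independent at the k centers.
    """
    if k < 2:
        raise InvalidParameterError(f"need at least 2 channels, got k={k}")
    if p is None:
        p = k - 1
    if p < 1:
        raise InvalidParameterError(f"exponent must be >= 1, got p={p}")
    centers = np.arange(k) * PERIOD_DEG / k
    return ChannelBasis(k=k, exponent=int(p), centers=centers, kind="unimodal")


def evaluate_basis(basis: ChannelBasis, design: StimulusDesign) -> np.ndarray:
    """Channel evaluation matrix C (s × k) at the design's distinct orientations."""
    return basis.evaluate(design.orientations)


def _circulant_condition(eigs: np.ndarray) -> float:
    moduli = np.abs(eigs)
    return float(moduli.max() / moduli.min())


def make_bimodal_transform(
    k: int = 8,
    lobe_shift: int = 3,
    secondary_gain: float = 0.9,
    eigen_floor: float = 1e-6,
) -> ChannelTransform:
    """Circulant transform P = I + g·Πᵐ turning each channel bimodal.

    Π is the one-step cyclic channel permutation, m = ``lobe_shift`` and
    g = ``secondary_gain``; each transformed channel acquires a secondary lobe
    m channel spacings (m·180/k degrees) away from its primary peak.  P is
    circulant, so its eigenvalues are 1 + g·e^{2πi·mq/k}; the construction is
    rejected as singular when any eigenvalue modulus falls below
    ``eigen_floor`` (e.g. g = 1 with m·k/gcd even makes P exactly singular).
    """
    if k < 2:
        raise InvalidParameterError(f"need at least 2 channels, got k={k}")
    if not 1 <= lobe_shift < k:
        raise InvalidParameterError(
            f"lobe_shift must satisfy 1 <= m < k, got m={lobe_shift}, k={k}"
        )
    if secondary_gain <= 0:
        raise InvalidParameterError(f"secondary_gain must be positive, got {secondary_gain}")
    q = np.arange(k)
    eigs = 1.0 + secondary_gain * np.exp(2j * np.pi * lobe_shift * q / k)
    if np.abs(eigs).min() < eigen_floor:
        raise SingularTransformError(
            f"bimodal transform (k={k}, m={lobe_shift}, g={secondary_gain}) is "
            f"singular or near-singular: min eigenvalue modulus "
            f"{np.abs(eigs).min():.3g} < floor {eigen_floor:g}"
        )
    pi_m = np.roll(np.eye(k), lobe_shift, axis=1)  # Π^m: column j gets channel j−m
    matrix = np.eye(k) + secondary_gain * pi_m
    return ChannelTransform(
        matrix=matrix, kind="bimodal", condition_number=_circulant_condition(eigs)
    )


def make_random_transform(
    k: int = 8,
    seed: int = 0,
    condition_ceiling: float = 1e3,
    max_retries: int = 100,
) -> ChannelTransform:
    """Random Gaussian k×k transform, redrawn until well conditioned.

    Entries are iid standard normal from the seeded generator; draws whose
    condition number reaches ``condition_ceiling`` are discarded (the
    generator advances) up to ``max_retries`` times.  Deterministic per seed.
    """
    if k < 2:
        raise InvalidParameterError(f"need at least 2 channels, got k={k}")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        matrix = rng.standard_normal((k, k))
        cond = float(np.linalg.cond(matrix))
        if cond < condition_ceiling:
            return ChannelTransform(matrix=matrix, kind="random", condition_number=cond)
    raise ConditioningError(
        f"no {k}x{k} random transform below condition ceiling {condition_ceiling:g} "
        f"in {max_retries} draws (seed {seed})"
    )


def transform_basis(basis: ChannelBasis, transform: ChannelTransform) -> ChannelBasis:
    """Transformed basis whose evaluation matrix is C₂ = C₁ P exactly."""
    if basis.kind != "unimodal":
        raise InvalidParameterError("only a unimodal basis can be transformed")
    if transform.k != basis.k:
        raise InvalidParameterError(
            f"transform dimension {transform.k} does not match basis k={basis.k}"
        )
    return ChannelBasis(
        k=basis.k,
        exponent=basis.exponent,
        centers=basis.centers,
        kind="transformed",
        transform=transform,
    )


# ---------------------------------------------------------------------------
# serialization


def basis_to_config(basis: ChannelBasis) -> dict:
    """Structured-text-ready description of a basis (and its parent transform)."""
    cfg: dict = {"kind": basis.kind, "k": int(basis.k), "p": int(basis.exponent)}
    if basis.kind == "transformed":
        cfg["transform"] = {
            "kind": basis.transform.kind,
            "matrix": basis.transform.matrix.tolist(),
            "condition_number": float(basis.transform.condition_number),
        }
    return cfg


def basis_from_config(cfg: dict) -> ChannelBasis:
    base = make_unimodal_basis(k=int(cfg["k"]), p=int(cfg["p"]))
    if cfg.get("kind", "unimodal") == "unimodal":
        return base
    tcfg = cfg["transform"]
    matrix = np.asarray(tcfg["matrix"], dtype=float)
    transform = ChannelTransform(
        matrix=matrix,
        kind=tcfg.get("kind", "custom"),
        condition_number=float(tcfg.get("condition_number", np.linalg.cond(matrix))),
    )
    return transform_basis(base, transform)


def export_basis_grid(basis: ChannelBasis, path, step_deg: float = 1.0) -> None:
    """Write the basis evaluated on a dense grid as delimited text.

    Columns: angle_deg, channel_index, value (long format).
    """
    import pandas as pd

    grid = np.arange(0.0, PERIOD_DEG, step_deg)
    values = basis.evaluate(grid)
    frames = pd.DataFrame(
        {
            "angle_deg": np.repeat(grid, basis.k),
            "channel_index": np.tile(np.arange(basis.k), grid.size),
            "value": values.ravel(),
        }
    )
    frames.to_csv(path, index=False)


def save_basis_config(basis: ChannelBasis, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(basis_to_config(basis), fh)


def load_basis_config(path) -> ChannelBasis:
    with open(path) as fh:
        return basis_from_config(yaml.safe_load(fh))
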