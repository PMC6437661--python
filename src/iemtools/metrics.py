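"""Circular statistics and curve-shape measures.

These operate on :class:`CircularCurve`, a uniformly sampled function on a
circular domain (period 180° for orientation).  Peak counts use a strict
circular-neighbor rule with deterministic plateau handling, so modality
claims never depend on smoothing; only the full width at half maximum uses
linear interpolation between grid points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, ModalityError

__all__ = [
    "CircularCurve",
    "circular_distance",
    "local_maxima",
    "peak_separation",
    "fwhm",
]


@dataclass(frozen=True)
class CircularCurve:
    """Values sampled at uniformly spaced offsets on a circle."""

    offsets: np.ndarray  # degrees
    values: np.ndarray
    period: float = 180.0

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if self.period <= 0:
            raise InvalidParameterError("period must be positive")
        if offsets.size != values.size:
            raise InvalidParameterError("offsets and values must have equal length")
        if offsets.size >= 2:
            steps = np.diff(offsets)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise InvalidParameterError("offsets must be uniformly spaced")
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "values", values)

    @property
    def spacing(self) -> float:
        return float(self.offsets[1] - self.offsets[0]) if self.offsets.size > 1 else self.period


def circular_distance(a: float, b: float, period: float = 180.0) -> float:
    """Minimal absolute angular difference on a circle of the given period.

    The result lies in [0, period/2]; adding any multiple of the period to
    either argument leaves it unchanged.
    """
    if period <= 0:
        raise InvalidParameterError("period must be positive")
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return float(np.minimum(d, period - d)) if np.ndim(d) == 0 else np.minimum(d, period - d)


def local_maxima(curve: CircularCurve) -> list[int]:
    """Indices of strict circular local maxima.

    A point is a maximum when its value strictly exceeds both circular
    neighbors; a plateau (run of equal adjacent values) counts once, at the
    smallest array index within the run, when both run neighbors are strictly
    lower.  A constant curve has no maxima.
    """
    values = curve.values
    n = values.size
    if n < 3:
        raise InvalidParameterError("need at least 3 points to find local maxima")
    if np.all(values == values[0]):
        return []
    # Segment the circle into runs of equal adjacent values (merging across
    # the wrap point), then compare each run against its neighboring runs.
    change = np.nonzero(values != np.roll(values, 1))[0]  # run start indices
    starts = change  # at least one exists since curve is non-constant
    run_values = values[starts]
    n_runs = starts.size
    maxima = []
    for r in range(n_runs):
        prev_v = run_values[(r - 1) % n_runs]
        next_v = run_values[(r + 1) % n_runs]
        if run_values[r] > prev_v and run_values[r] > next_v:
            start = starts[r]
            end = starts[(r + 1) % n_runs]
            run_idx = np.arange(start, start + (end - start) % n or n) % n
            maxima.append(int(run_idx.min()))
    return sorted(maxima)


def peak_separation(curve: CircularCurve) -> float:
    """Circular distance in degrees between the two local maxima of a bimodal curve."""
    peaks = local_maxima(curve)
    if len(peaks) != 2:
        raise ModalityError(f"peak separation requires exactly 2 local maxima, found {len(peaks)}")
    return circular_distance(curve.offsets[peaks[0]], curve.offsets[peaks[1]], curve.period)


def fwhm(curve: CircularCurve) -> float:
    """Full width at half maximum of a unimodal circular curve, in degrees.

    The half height is (max + min)/2; the width is measured around the global
    maximum, with linear interpolation between the grid points that bracket
    each half-height crossing.  A curve that never crosses the half height
    (e.g. constant) raises :class:`ModalityError`.
    """
    values = curve.values
    n = values.size
    if n < 3:
        raise InvalidParameterError("need at least 3 points for a width")
    vmax, vmin = values.max(), values.min()
    if vmax == vmin:
        raise ModalityError("constant curve has no half-height crossing")
    half = 0.5 * (vmax + vmin)
    peak = int(np.argmax(values))
    spacing = curve.spacing

    def _steps_to_crossing(direction: int) -> float:
        prev = values[peak]
        for step in range(1, n):
            cur = values[(peak + direction * step) % n]
            if cur < half:
                # linear interpolation between the bracketing grid points
                frac = (prev - half) / (prev - cur)
                return (step - 1) + frac
            prev = cur
        raise ModalityError("curve never falls below half height around the peak")

    right = _steps_to_crossing(+1)
    left = _steps_to_crossing(-1)
    return float((right + left) * spacing)
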