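"""Kneedle-style knee-point detection for decreasing consistency curves.

The construction: fit a cubic smoothing spline to (n, SD̄_spatial), min-max
normalize both axes to the unit square, and find the observed sample that
maximizes the vertical distance between the smoothed curve and the straight
chord joining its first and last normalized points. For a convex decreasing
curve the chord lies above the curve and the maximizer is the point of
diminishing returns. The reported knee is always one of the observed n
values — no sub-sample interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline, make_smoothing_spline

from .errors import KneeInputError

#: below this maximal chord distance (on normalized axes) no knee is declared
DEFAULT_DISTANCE_THRESHOLD = 0.01


@dataclass
class KneePoint:
    """Result of knee detection on one curve."""

    n_at_knee: int | None
    distance: float
    smoothed_curve: np.ndarray
    found: bool


def fit_smoothing_spline(x, y, smoothing: float | None = None) -> np.ndarray:
    """Cubic smoothing spline evaluated at the input x.

    ``smoothing=None`` selects the regularization parameter automatically by
    generalized cross-validation; ``smoothing=0`` interpolates (returns y at
    the input x exactly); positive values are passed to the classic
    residual-budget smoothing-spline formulation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise KneeInputError("x and y must be 1D arrays of equal length")
    if x.size < 4:
        raise KneeInputError(f"need >= 4 points for a cubic spline, got {x.size}")
    if not (np.diff(x) > 0).all():
        raise KneeInputError("x must be strictly increasing")
    if smoothing is None:
        spline = make_smoothing_spline(x, y)  # GCV-selected lambda
        return np.asarray(spline(x), dtype=float)
    if smoothing < 0:
        raise KneeInputError(f"smoothing must be >= 0, got {smoothing}")
    if smoothing == 0:
        return y.copy()  # an interpolating spline passes through the data
    spline = UnivariateSpline(x, y, k=3, s=float(smoothing))
    return np.asarray(spline(x), dtype=float)


def normalize_curve(x, y):
    """Min-max normalize both axes to [0, 1].

    Degenerate (flat) axes raise; :func:`find_knee` turns a flat-y curve
    into ``found=False`` instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xspan = x.max() - x.min()
    yspan = y.max() - y.min()
    if xspan <= 0:
        raise KneeInputError("cannot normalize: x has zero range")
    if yspan <= 0:
        raise KneeInputError("cannot normalize: y has zero range (flat curve)")
    return (x - x.min()) / xspan, (y - y.min()) / yspan


def chord_distances(x_hat, y_hat) -> np.ndarray:
    """Vertical distance from the curve to the first-to-last chord.

    Positive where the curve dips below the chord (the knee side of a
    decreasing convex curve); this is the Kneedle difference curve up to the
    fixed sign convention.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    x0, y0 = x_hat[0], y_hat[0]
    x1, y1 = x_hat[-1], y_hat[-1]
    chord = y0 + (y1 - y0) * (x_hat - x0) / (x1 - x0)
    return chord - y_hat


def find_knee(
    curve,
    smoothing: float | None = None,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    perpendicular: bool = False,
) -> KneePoint:
    """Knee of a consistency curve (or any decreasing sampled curve).

    Accepts a :class:`~normmap.consistency.ConsistencyCurve` or an ``(x, y)``
    pair. Ties in the maximal distance break toward smaller n. When the
    maximal distance does not exceed ``distance_threshold`` (e.g. the curve
    is a straight line) no knee is declared.

    ``perpendicular=True`` measures point-to-chord perpendicular distance
    instead of vertical distance; on normalized axes the argmax rarely
    differs.
    """
    if hasattr(curve, "n_values"):
        x = curve.n_values.astype(float)
        y = curve.sd_values
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    smoothed = fit_smoothing_spline(x, y, smoothing=smoothing)
    if smoothed.max() - smoothed.min() <= 0:
        return KneePoint(n_at_knee=None, distance=0.0,
                         smoothed_curve=smoothed, found=False)
    x_hat, y_hat = normalize_curve(x, smoothed)
    dist = chord_distances(x_hat, y_hat)
    if perpendicular:
        # chord direction is (1, y1-y0)/|.| on normalized axes
        slope = y_hat[-1] - y_hat[0]
        dist = dist / np.sqrt(1.0 + slope**2)
    best = int(np.argmax(dist))  # argmax returns the first (smallest-n) tie
    best_dist = float(dist[best])
    if best_dist <= distance_threshold:
        return KneePoint(n_at_knee=None, distance=max(best_dist, 0.0),
                         smoothed_curve=smoothed, found=False)
    return KneePoint(
        n_at_knee=int(round(x[best])),
        distance=best_dist,
        smoothed_curve=smoothed,
        found=True,
    )
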