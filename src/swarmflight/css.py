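"""Curvature scale space (CSS) shape descriptor.

The CSS of a planar curve records where the curvature changes sign
(inflection points) as the curve is progressively smoothed by Gaussian
kernels of increasing width sigma.  Plotting zero-crossing locations in the
(u, sigma) plane — u being normalised arc length — yields the CSS image,
whose ridges are robust to translation, rotation and uniform scaling.

Here each track segment is projected onto the XY, YZ and XZ planes,
re-parameterised to uniform arc length, and its CSS image reduced to a 1D
signal: for every u-bin the largest sigma at which a curvature zero crossing
occurs (0 where none does).  The mean and standard deviation of that signal,
averaged over the three planes, enter the feature set.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Defaults: 16 log-spaced smoothing widths (in resampled-sample units) and
#: 64 arc-length bins; both configurable.
DEFAULT_SIGMA_GRID = tuple(np.geomspace(0.5, 8.0, 16))
DEFAULT_N_BINS = 64

PLANE_INDICES = ((0, 1), (1, 2), (0, 2))


@lru_cache(maxsize=128)
def _gaussian_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray, int]:
    """First- and second-derivative Gaussian kernels (edge-padded convolution
    with these equals Gaussian smoothing followed by differentiation)."""
    radius = int(4.0 * sigma + 0.5)
    t = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * (t / sigma) ** 2)
    phi /= phi.sum()
    k1 = -t / sigma**2 * phi
    k2 = (t**2 / sigma**4 - 1.0 / sigma**2) * phi
    return k1, k2, radius


def _smoothed_derivatives(x: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    k1, k2, radius = _gaussian_kernels(float(sigma))
    xp = np.pad(x, radius, mode="edge")
    return np.convolve(xp, k1, mode="valid"), np.convolve(xp, k2, mode="valid")


def resample_arclength(coords: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Resample a 2D polyline at `n_bins` uniform normalised-arc-length points.

    Returns None when the projected path has (numerically) zero length, in
    which case the curve has no inflections by convention.
    """
    steps = np.diff(coords, axis=0)
    seglen = np.linalg.norm(steps, axis=1)
    total = seglen.sum()
    if total <= 0:
        return None
    s = np.concatenate([[0.0], np.cumsum(seglen)]) / total
    u = np.linspace(0.0, 1.0, n_bins)
    out = np.empty((n_bins, 2))
    out[:, 0] = np.interp(u, s, coords[:, 0])
    out[:, 1] = np.interp(u, s, coords[:, 1])
    return out


def css_signal(
    coords: np.ndarray,
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    n_bins: int = DEFAULT_N_BINS,
) -> np.ndarray:
    """Column-maximum CSS signal of one 2D curve.

    signal[u] = max sigma in the grid at which the smoothed curvature
    changes sign within bin u; 0 if no crossing ever occurs there.  The
    curvature sign is taken from its numerator x' y'' - y' x'' (the
    denominator is positive), so zero crossings are scale invariant.
    """
    if len(sigma_grid) == 0:
        raise ValueError("sigma_grid must be non-empty")
    if np.any(np.diff(sigma_grid) <= 0) or sigma_grid[0] <= 0:
        raise ValueError("sigma_grid must be ascending and positive")
    curve = resample_arclength(np.asarray(coords, dtype=float), n_bins)
    signal = np.zeros(n_bins)
    if curve is None:
        return signal
    # centre and scale to unit bounding-box diagonal: zero crossings are
    # invariant to translation/scaling, and normalising makes the numerical
    # noise floor well defined (straight curves must yield no crossings)
    curve = curve - curve.mean(axis=0)
    diag = float(np.linalg.norm(curve.max(axis=0) - curve.min(axis=0)))
    if diag <= 0:
        return signal
    curve = curve / diag
    x, y = curve[:, 0], curve[:, 1]
    for sigma in sigma_grid:
        x1, x2 = _smoothed_derivatives(x, sigma)
        y1, y2 = _smoothed_derivatives(y, sigma)
        numerator = x1 * y2 - y1 * x2
        numerator[np.abs(numerator) < 1e-12] = 0.0
        s = np.sign(numerator)
        crossing = (s[:-1] != s[1:]) & (s[:-1] != 0) & (s[1:] != 0)
        signal[:-1][crossing] = sigma  # grid ascends: later sigmas overwrite
    return signal


def css_summary(
    positions: np.ndarray,
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[float, float]:
    """Mean and standard deviation of the CSS signal, averaged over the XY,
    YZ and XZ projections of a 3D segment."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 8:
        return float("nan"), float("nan")
    means, stds = [], []
    for i, j in PLANE_INDICES:
        signal = css_signal(positions[:, (i, j)], sigma_grid, n_bins)
        means.append(float(np.mean(signal)))
        stds.append(float(np.std(signal, ddof=1)))
    return float(np.mean(means)), float(np.mean(stds))
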