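"""Curvature analysis of breast margins and elliptical snake initialization.

The signed curvature along each margin chain is

    k = (x' y'' - x'' y') / (x'^2 + y'^2)^(3/2)

with derivatives taken with respect to the chain parameter after 1-D
Gaussian smoothing of the coordinates (the expression is invariant to the
parametrization, so uniform-in-index differentiation is adequate for pixel
chains).  With the margin orientation convention of :mod:`thermoseg.io_prep`
a convex arc has k > 0 on the right margin and k < 0 on the left margin, so
the delimiting "peaks of interest" are curvature maxima on the right side
and minima on the left side.  The margin points between the outermost peaks
are fitted with a direct least-squares ellipse, which — radially contracted
by a small factor — seeds the GVF snake just inside the breast boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d
from skimage.measure import EllipseModel

from .errors import InitializationError, ParameterError
from .io_prep import BoundaryCurve


@dataclass
class CurvatureProfile:
    """Per-point curvature along a closed boundary curve.

    Attributes
    ----------
    k : signed curvature, 1/pixels, one value per curve point
    s : cumulative arc length in pixels (strictly increasing, s[0] = 0)
    theta : tangent angle in radians
    curve : the source curve (kept for peak -> point lookup)
    """

    k: np.ndarray
    s: np.ndarray
    theta: np.ndarray
    curve: BoundaryCurve


@dataclass
class EllipseInit:
    """Initial ellipse for one breast: center, semi-axes (a >= b), rotation."""

    center: tuple
    a: float
    b: float
    rotation: float
    side: str


@dataclass
class SnakeContour:
    """Closed snake polygon with sub-pixel vertices, shape (N, 2) as (x, y)."""

    vertices: np.ndarray

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.vertices)


def curvature(curve: BoundaryCurve, smooth_sigma: float = 3.0) -> CurvatureProfile:
    """Signed curvature profile of a closed boundary curve.

    Coordinates are smoothed circularly with a Gaussian of ``smooth_sigma``
    points; first and second derivatives are the analytic derivatives of the
    smoothed coordinate signals.  Degenerate (collinear) curves yield a
    near-zero profile rather than an error.
    """
    pts = np.asarray(curve.points, dtype=float)
    if len(pts) < 5:
        raise ParameterError("curvature needs a curve with at least 5 points")
    x, y = pts[:, 0], pts[:, 1]
    if smooth_sigma > 0:
        x = gaussian_filter1d(x, smooth_sigma, mode="wrap")
        y = gaussian_filter1d(y, smooth_sigma, mode="wrap")

    def d1(z):  # circular central first difference
        return 0.5 * (np.roll(z, -1) - np.roll(z, 1))

    def d2(z):  # circular central second difference
        return np.roll(z, -1) - 2.0 * z + np.roll(z, 1)

    dx, dy, ddx, ddy = d1(x), d1(y), d2(x), d2(y)
    speed_sq = dx * dx + dy * dy
    denom = np.power(speed_sq, 1.5)
    tiny = np.finfo(float).tiny
    k = (dx * ddy - ddx * dy) / np.maximum(denom, tiny)
    k[speed_sq < 1e-12] = 0.0
    seg = np.sqrt(np.sum(np.diff(pts, axis=0) ** 2, axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])[: len(pts)]
    theta = np.arctan2(dy, dx)
    return CurvatureProfile(k=k, s=s, theta=theta, curve=curve)


def find_peaks(
    profile: CurvatureProfile,
    side: str | None = None,
    min_prominence: float = 0.005,
) -> np.ndarray:
    """Indices of the delimiting curvature peaks, in arc-length order.

    For ``side="right"`` local maxima of ``k`` with prominence and height at
    least ``min_prominence``; for ``side="left"`` local minima of ``k``
    below ``-min_prominence``.  The profile is treated as circular.  A
    constant profile has no peaks and yields an empty array.
    """
    if side is None:
        side = profile.curve.side
    if side not in ("left", "right"):
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    sig = profile.k if side == "right" else -profile.k
    n = len(sig)
    if n == 0:
        return np.array([], dtype=int)
    # rotate so the circular scan starts at the global minimum: no peak is
    # split across the wrap point
    shift = int(np.argmin(sig))
    rolled = np.roll(sig, -shift)
    idx, _ = signal.find_peaks(
        rolled, height=min_prominence, prominence=min_prominence
    )
    peaks = np.sort((idx + shift) % n)
    return peaks


def fit_initial_ellipse(
    peak_points: np.ndarray,
    curve: BoundaryCurve,
    side: str,
    min_arc_fraction: float = 0.25,
) -> EllipseInit:
    """Fit the initial breast ellipse to the margin arc between the peaks.

    ``peak_points`` may be given as indices into the curve or as (x, y)
    coordinates of curve points.  The fitted arc runs forward from the first
    to the last peak (inclusive); if that span covers less than
    ``min_arc_fraction`` of the curve the complementary arc is used.

    Raises
    ------
    InitializationError
        With fewer than two delimiting peaks, or when the least-squares
        conic through the arc is degenerate (not an ellipse).
    """
    pts = np.asarray(curve.points, dtype=float)
    n = len(pts)
    peak_points = np.asarray(peak_points)
    if peak_points.size == 0 or len(np.atleast_1d(peak_points)) < 2:
        raise InitializationError(f"{side} margin: need >= 2 delimiting peaks")
    if peak_points.ndim == 2:  # coordinates -> indices
        idx = []
        for p in peak_points:
            d = np.sum((pts - p[None, :]) ** 2, axis=1)
            idx.append(int(np.argmin(d)))
        idx = np.sort(np.array(idx))
    else:
        idx = np.sort(peak_points.astype(int))
    i0, i1 = int(idx[0]), int(idx[-1])
    span = i1 - i0 + 1
    if span < min_arc_fraction * n:
        arc = np.concatenate([pts[i1:], pts[: i0 + 1]], axis=0)
    else:
        arc = pts[i0 : i1 + 1]
    if len(arc) < 5:
        raise InitializationError(f"{side} margin: arc between peaks too short")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(arc)
        if not model:  # FailedEstimation is falsy
            raise InitializationError(f"{side} margin: degenerate conic fit")
        (xc, yc), (a, b), theta = (model.center, model.axis_lengths,
                                   model.theta)
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(arc) or model.params is None:
            raise InitializationError(f"{side} margin: degenerate conic fit")
        xc, yc, a, b, theta = model.params
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise InitializationError(f"{side} margin: degenerate conic fit")
    if a <= 0 or b <= 0:
        raise InitializationError(f"{side} margin: degenerate conic fit")
    if b > a:  # normalize so a is the semi-major axis
        a, b = b, a
        theta = theta + np.pi / 2.0
    theta = float(np.arctan2(np.sin(theta), np.cos(theta)))
    return EllipseInit(center=(float(xc), float(yc)), a=float(a), b=float(b),
                       rotation=theta, side=side)


def initial_ellipse_from_curve(
    curve: BoundaryCurve,
    smooth_sigma: float = 3.0,
    min_prominence: float = 0.005,
) -> EllipseInit:
    """Curvature peaks -> delimiting points -> fitted ellipse, with fallback.

    When no peak exceeds the prominence floor the two points of extreme
    correctly-signed curvature are used as delimiters.
    """
    prof = curvature(curve, smooth_sigma=smooth_sigma)
    peaks = find_peaks(prof, side=curve.side, min_prominence=min_prominence)
    if len(peaks) < 2:
        sig = prof.k if curve.side == "right" else -prof.k
        order = np.argsort(sig)[::-1]
        cand = order[sig[order] > 0][:2]
        if len(cand) < 2:
            raise InitializationError(
                f"{curve.side} margin: no usable curvature peaks"
            )
        peaks = np.sort(cand)
    return fit_initial_ellipse(peaks, curve, curve.side)


def contract_to_snake(
    ellipse: EllipseInit,
    factor: float = 0.95,
    n_vertices: int = 200,
    image_shape: tuple | None = None,
) -> SnakeContour:
    """Sample the contracted ellipse as the initial snake polygon.

    Both semi-axes are scaled by ``factor`` (uniform radial contraction) and
    the ellipse is sampled at ``n_vertices`` equally spaced parameter
    values.  With ``image_shape=(H, W)`` vertices are clipped to the image.
    """
    if not 0.0 < factor <= 1.0:
        raise ParameterError(f"contraction factor must lie in (0, 1], got {factor}")
    if n_vertices < 16:
        raise ParameterError(f"need at least 16 snake vertices, got {n_vertices}")
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    cr, sr = np.cos(ellipse.rotation), np.sin(ellipse.rotation)
    a = factor * ellipse.a
    b = factor * ellipse.b
    x = ellipse.center[0] + a * ct * cr - b * st * sr
    y = ellipse.center[1] + a * ct * sr + b * st * cr
    verts = np.stack([x, y], axis=1)
    if image_shape is not None:
        h, w = image_shape[:2]
        verts[:, 0] = np.clip(verts[:, 0], 0.0, w - 1.0)
        verts[:, 1] = np.clip(verts[:, 1], 0.0, h - 1.0)
    return SnakeContour(vertices=verts)
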