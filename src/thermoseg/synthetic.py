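"""Seeded synthetic breast-thermogram phantoms with ground-truth masks.

A phantom is a scalar "temperature" field in [0, 1] rendered through a
fixed, invertible blue-green-red pseudo-colour palette:

* a cold surround (default 0.02),
* a torso-shaped warm background (default 0.10 — warm, but below the
  level at which the gray working copy crosses the 0.25 binarization
  threshold),
* two elliptical breast regions, one per image half, elevated by a fixed
  amount (default +0.30) so they are the only regions the threshold
  isolates,
* for abnormal cases, a localized Gaussian hot spot inside one breast
  (default +0.30), producing the intensity and colour asymmetry that the
  relation-context features and classifiers key on,
* additive seeded Gaussian noise, clipped to [0, 1].

Ground-truth masks are rasterized from the exact breast ellipses; the
rendered field uses slightly smoothed ellipse edges so the gray image has
a finite edge width for the GVF snake to lock onto.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy import ndimage

from .errors import ParameterError, PhantomSpecError


@dataclass
class EllipseRegion:
    """One breast ellipse: center (x, y), semi-axes (a, b), rotation (rad)."""

    center: tuple
    axes: tuple
    rotation: float = 0.0


@dataclass
class HotSpot:
    present: bool = False
    offset: tuple = (0.0, 0.0)  # (dx, dy) from the host breast center
    radius: float = 6.0  # Gaussian sigma, pixels
    elevation: float = 0.30
    side: str = "left"


@dataclass
class PhantomSpec:
    shape: tuple = (192, 256)  # (H, W)
    left: EllipseRegion = field(default_factory=lambda: EllipseRegion(
        center=(72.0, 118.0), axes=(32.0, 42.0), rotation=0.0))
    right: EllipseRegion = field(default_factory=lambda: EllipseRegion(
        center=(184.0, 118.0), axes=(32.0, 42.0), rotation=0.0))
    background_level: float = 0.10  # torso temperature
    surround_level: float = 0.02  # off-body temperature
    breast_elevation: float = 0.30
    edge_softness: float = 1.0  # Gaussian sigma applied to the field, pixels
    noise_sd: float = 0.01
    hot_spot: HotSpot = field(default_factory=HotSpot)
    seed: int = 0

    @property
    def label(self) -> str:
        return "abnormal" if self.hot_spot.present else "normal"


@dataclass
class PhantomSample:
    image: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    label: str
    spec: PhantomSpec
    temperature: np.ndarray


def pseudo_color(fld: np.ndarray) -> np.ndarray:
    """Map a [0, 1] scalar field through the blue-green-red palette.

    Piecewise linear: 0 -> (0,0,1), 0.5 -> (0,1,0), 1 -> (1,0,0); strictly
    monotone in hue position and invertible on [0, 1].
    """
    t = np.asarray(fld, dtype=np.float64)
    if t.min() < 0.0 or t.max() > 1.0:
        raise ParameterError("pseudo_color expects values in [0, 1]")
    lo = t <= 0.5
    r = np.where(lo, 0.0, 2.0 * t - 1.0)
    g = np.where(lo, 2.0 * t, 2.0 - 2.0 * t)
    b = np.where(lo, 1.0 - 2.0 * t, 0.0)
    return np.stack([r, g, b], axis=-1)


def invert_pseudo_color(rgb: np.ndarray) -> np.ndarray:
    """Recover the temperature field from a palette-rendered RGB image."""
    rgb = np.asarray(rgb, dtype=np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    low = (g + 1.0 - b) / 4.0
    high = (3.0 + r - g) / 4.0
    return np.where(r > b, high, low)


def _ellipse_field(shape, region: EllipseRegion) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx = xx - region.center[0]
    dy = yy - region.center[1]
    cr, sr = np.cos(region.rotation), np.sin(region.rotation)
    xr = dx * cr + dy * sr
    yr = -dx * sr + dy * cr
    a, b = region.axes
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _validate(spec: PhantomSpec) -> None:
    h, w = spec.shape
    if spec.noise_sd < 0:
        raise PhantomSpecError("noise sd must be >= 0")
    mid = w / 2.0
    for region, side in ((spec.left, "left"), (spec.right, "right")):
        cx, cy = region.center
        a, b = region.axes
        if a <= 0 or b <= 0:
            raise PhantomSpecError(f"{side} breast semi-axes must be positive")
        reach = max(a, b)
        if not (reach <= cx <= w - 1 - reach and reach <= cy <= h - 1 - reach):
            raise PhantomSpecError(f"{side} breast does not fit inside the image")
        if side == "left" and cx >= mid:
            raise PhantomSpecError("left breast center is in the right half")
        if side == "right" and cx < mid:
            raise PhantomSpecError("right breast center is in the left half")
    lm = _ellipse_field(spec.shape, spec.left)
    rm = _ellipse_field(spec.shape, spec.right)
    if (lm & rm).any():
        raise PhantomSpecError("breast ellipses overlap")
    if spec.hot_spot.present:
        host = spec.left if spec.hot_spot.side == "left" else spec.right
        hx = host.center[0] + spec.hot_spot.offset[0]
        hy = host.center[1] + spec.hot_spot.offset[1]
        mask = lm if spec.hot_spot.side == "left" else rm
        ix, iy = int(round(hx)), int(round(hy))
        if not (0 <= iy < h and 0 <= ix < w and mask[iy, ix]):
            raise PhantomSpecError("hot spot center lies outside its breast")


def render_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom: pseudo-colour image plus exact truth masks."""
    _validate(spec)
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    torso = EllipseRegion(center=((w - 1) / 2.0, (h - 1) / 2.0),
                          axes=(0.42 * w, 0.48 * h))
    field_ = np.full((h, w), spec.surround_level)
    field_[_ellipse_field(spec.shape, torso)] = spec.background_level
    left_mask = _ellipse_field(spec.shape, spec.left)
    right_mask = _ellipse_field(spec.shape, spec.right)
    field_[left_mask] += spec.breast_elevation
    field_[right_mask] += spec.breast_elevation
    if spec.edge_softness > 0:
        field_ = ndimage.gaussian_filter(field_, spec.edge_softness,
                                         mode="nearest")
    if spec.hot_spot.present:
        host = spec.left if spec.hot_spot.side == "left" else spec.right
        hx = host.center[0] + spec.hot_spot.offset[0]
        hy = host.center[1] + spec.hot_spot.offset[1]
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        d2 = (xx - hx) ** 2 + (yy - hy) ** 2
        field_ = field_ + spec.hot_spot.elevation * np.exp(
            -d2 / (2.0 * spec.hot_spot.radius**2))
    if spec.noise_sd > 0:
        field_ = field_ + rng.normal(0.0, spec.noise_sd, size=field_.shape)
    field_ = np.clip(field_, 0.0, 1.0)
    image = pseudo_color(field_)
    return PhantomSample(image=image, left_mask=left_mask,
                         right_mask=right_mask, label=spec.label, spec=spec,
                         temperature=field_)


@dataclass
class JitterRanges:
    """Seeded per-sample variation applied by :func:`make_dataset`."""

    center: float = 6.0  # max |dx|, |dy| shift of each breast center, px
    axis_scale: tuple = (0.9, 1.1)  # multiplicative semi-axis range
    rotation: float = 0.15  # max |rotation|, radians
    elevation: float = 0.05  # max breast-elevation perturbation
    hot_spot_elevation: float = 0.05
    hot_spot_radius: tuple = (5.0, 8.0)
    hot_spot_offset_frac: float = 0.35  # of the host semi-axes


def make_dataset(n_normal: int, n_abnormal: int,
                 jitter: JitterRanges | None = None, seed: int = 0,
                 base: PhantomSpec | None = None) -> list:
    """Generate a labelled phantom dataset with seeded jitter.

    Returns ``n_normal`` normal samples followed by ``n_abnormal`` abnormal
    ones; all randomness (spec jitter, rendering noise) flows from ``seed``.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ParameterError("sample counts must be >= 0")
    jitter = jitter or JitterRanges()
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    samples = []
    labels = ["normal"] * n_normal + ["abnormal"] * n_abnormal
    for k, label in enumerate(labels):
        spec = _jittered_spec(base, jitter, label, rng)
        try:
            _validate(spec)
        except PhantomSpecError as exc:
            raise PhantomSpecError(
                f"jitter ranges made sample {k} infeasible: {exc}") from exc
        samples.append(render_phantom(spec))
    return samples


def _jittered_spec(base: PhantomSpec, jit: JitterRanges, label: str,
                   rng: np.random.Generator) -> PhantomSpec:
    def jitter_region(region: EllipseRegion) -> EllipseRegion:
        dx, dy = rng.uniform(-jit.center, jit.center, size=2)
        sa, sb = rng.uniform(*jit.axis_scale, size=2)
        rot = rng.uniform(-jit.rotation, jit.rotation)
        return EllipseRegion(
            center=(region.center[0] + dx, region.center[1] + dy),
            axes=(region.axes[0] * sa, region.axes[1] * sb),
            rotation=region.rotation + rot)

    left = jitter_region(base.left)
    right = jitter_region(base.right)
    elev = base.breast_elevation + rng.uniform(-jit.elevation, jit.elevation)
    if label == "abnormal":
        side = "left" if rng.random() < 0.5 else "right"
        host = left if side == "left" else right
        frac = jit.hot_spot_offset_frac
        off = (rng.uniform(-frac, frac) * host.axes[0],
               rng.uniform(-frac, frac) * host.axes[1])
        hs = HotSpot(
            present=True, offset=off,
            radius=rng.uniform(*jit.hot_spot_radius),
            elevation=base.hot_spot.elevation + rng.uniform(
                -jit.hot_spot_elevation, jit.hot_spot_elevation),
            side=side)
    else:
        hs = HotSpot(present=False)
    return replace(base, left=left, right=right, breast_elevation=elev,
                   hot_spot=hs, seed=int(rng.integers(0, 2**31 - 1)))


def spec_record(spec: PhantomSpec) -> dict:
    """Flat JSON-friendly echo of a phantom spec (for manifests)."""
    d = asdict(spec)
    d["label"] = spec.label
    return d
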