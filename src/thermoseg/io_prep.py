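"""Image I/O and preprocessing for breast thermograms.

The pipeline front end: load a pseudo-colour thermogram, convert to a gray
working copy, denoise with a small Gaussian kernel, binarize at a fixed
intensity threshold, and trace the left/right breast margins as ordered
closed boundary curves.

Conventions
-----------
* Images are numpy arrays in ``[0, 1]``: RGB is ``(H, W, 3)`` float, gray is
  ``(H, W)`` float, masks are ``(H, W)`` bool.
* Points are ``(x, y)`` with ``x`` = column, ``y`` = row, 0-based.
* Boundary curves are closed 8-connected pixel chains.  The right-side
  margin is stored with positive signed (shoelace) area in ``(x, y)``
  coordinates, the left-side margin with negative signed area, so that
  convex breast arcs have positive curvature on the right margin and
  negative curvature on the left margin (the peak-sign convention used by
  the curvature-based initializer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .errors import (
    AmbiguousSceneError,
    EmptySceneError,
    ImageReadError,
    ParameterError,
)

#: Rec. 601 luminance weights used for RGB -> gray conversion
#: (normalized to sum exactly to 1 so white maps to 1.0).
LUMA_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])
LUMA_WEIGHTS = LUMA_WEIGHTS / LUMA_WEIGHTS.sum()

#: Minimum pixel count for a connected component to count as a margin.
MIN_COMPONENT_AREA = 20


@dataclass
class BoundaryCurve:
    """Ordered closed boundary of one breast margin.

    Attributes
    ----------
    points : (N, 2) float array of ``(x, y)`` pixel coordinates.  The chain
        is closed implicitly (last point is 8-adjacent to the first) and
        contains no repeated consecutive points.
    side : ``"left"`` or ``"right"`` — image half of the curve centroid.
    orientation : sign of the signed polygon area (+1 or -1).
    """

    points: np.ndarray
    side: str
    orientation: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.points)

    def reversed(self) -> "BoundaryCurve":
        """Same curve traversed in the opposite direction."""
        return BoundaryCurve(self.points[::-1].copy(), self.side, -self.orientation)


def signed_area(points: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as an (N, 2) ``(x, y)`` array."""
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def load_image(path) -> np.ndarray:
    """Load a JPEG/PNG image as an ``(H, W, 3)`` float array in [0, 1].

    Single-channel inputs are replicated to three channels; an alpha
    channel, if present, is dropped.
    """
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageReadError(f"cannot read image file {path!r}: {exc}") from exc
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.clip(arr, 0.0, 1.0)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to gray with standard luminance weights."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ParameterError("to_gray expects an (H, W, 3) RGB array")
    return img @ LUMA_WEIGHTS


def denoise(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Gaussian-smooth a gray image with a ``kernel`` x ``kernel`` filter.

    The Gaussian sigma is ``kernel / 6`` rounded to the nearest half pixel
    (3-sigma support inside the kernel); ``kernel=1`` is the identity.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"kernel must be an odd positive integer, got {kernel}")
    img = np.asarray(img, dtype=np.float64)
    if kernel == 1:
        return img.copy()
    sigma = max(round(kernel / 6.0 * 2) / 2.0, 0.5)
    truncate = ((kernel - 1) / 2.0) / sigma
    return ndimage.gaussian_filter(img, sigma=sigma, truncate=truncate, mode="reflect")


def binarize(img: np.ndarray, threshold: float = 0.25) -> np.ndarray:
    """Threshold a gray image: foreground where intensity > ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold}")
    return np.asarray(img, dtype=np.float64) > threshold


# ---------------------------------------------------------------------------
# boundary tracing

# Moore neighbourhood in clockwise order starting West, as (dr, dc)
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of the foreground of ``mask``.

    Moore-neighbour tracing with Jacob's stopping criterion.  Returns an
    (N, 2) integer array of ``(x, y)`` points forming a closed 8-connected
    chain without repeated consecutive points.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptySceneError("mask has no foreground")
    # first foreground pixel in raster order: its West neighbour is background
    i = np.lexsort((cols, rows))[0]
    start = (int(rows[i]), int(cols[i]))
    h, w = mask.shape

    def fg(r, c):
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    chain = [start]
    cur = start
    back_idx = 0  # index into _MOORE of the backtrack direction (West)
    start_back = back_idx
    while True:
        found = False
        for step in range(1, 9):
            j = (back_idx + step) % 8
            dr, dc = _MOORE[j]
            r, c = cur[0] + dr, cur[1] + dc
            if fg(r, c):
                # new backtrack: the (background) neighbour examined just
                # before the hit, expressed relative to the new pixel
                prev = (cur[0] + _MOORE[(j - 1) % 8][0], cur[1] + _MOORE[(j - 1) % 8][1])
                cur = (r, c)
                back_idx = _moore_index(cur, prev)
                found = True
                break
        if not found:  # isolated pixel
            break
        if cur == start and back_idx == start_back:
            break
        if cur == chain[0] and len(chain) > 2:
            break
        chain.append(cur)
        if len(chain) > 4 * mask.size:  # pragma: no cover - safety valve
            raise RuntimeError("boundary tracing did not terminate")
    pts = np.array([(c, r) for r, c in chain], dtype=float)
    return pts


def _moore_index(center, neighbour) -> int:
    dr = neighbour[0] - center[0]
    dc = neighbour[1] - center[1]
    return _MOORE.index((dr, dc))


def _oriented(points: np.ndarray, side: str) -> BoundaryCurve:
    """Orient a traced chain per the side convention (right: +, left: -)."""
    area = signed_area(points)
    want = 1 if side == "right" else -1
    if area != 0 and np.sign(area) != want:
        points = points[::-1].copy()
    return BoundaryCurve(points=points, side=side, orientation=want)


def extract_margins(mask: np.ndarray, gray: np.ndarray | None = None):
    """Extract the left and right breast margin curves from a binary mask.

    Accepts either one dominant foreground component spanning both image
    halves (split at the vertical midline into two margins) or two
    components, one per half.  Components smaller than
    ``MIN_COMPONENT_AREA`` pixels are ignored as noise.

    Returns ``(left_curve, right_curve)``.  ``gray`` is accepted for
    interface compatibility (an edge-detection backend would use it) but the
    default backend traces the thresholded components directly.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise EmptySceneError("binary mask contains no foreground component")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    usable = [i + 1 for i, s in enumerate(sizes) if s >= MIN_COMPONENT_AREA]
    if not usable:
        raise EmptySceneError("no foreground component above the size floor")
    if len(usable) > 2:
        raise AmbiguousSceneError(
            f"expected 1 or 2 usable foreground components, found {len(usable)}"
        )
    mid = mask.shape[1] / 2.0
    if len(usable) == 1:
        comp = labels == usable[0]
        cols = np.nonzero(comp)[1]
        if cols.min() >= mid or cols.max() < mid:
            raise AmbiguousSceneError(
                "single foreground component does not span both image halves"
            )
        left_half = comp.copy()
        left_half[:, int(np.ceil(mid)):] = False
        right_half = comp.copy()
        right_half[:, : int(np.ceil(mid))] = False
        parts = {"left": _largest_component(left_half),
                 "right": _largest_component(right_half)}
    else:
        parts = {}
        for lab in usable:
            comp = labels == lab
            cx = np.nonzero(comp)[1].mean()
            side = "left" if cx < mid else "right"
            if side in parts:
                raise AmbiguousSceneError(
                    "two foreground components lie in the same image half"
                )
            parts[side] = comp
        if set(parts) != {"left", "right"}:
            raise AmbiguousSceneError(
                "could not attribute one component to each image half"
            )
    curves = {}
    for side, comp in parts.items():
        pts = trace_boundary(comp)
        if len(pts) < 3:
            raise EmptySceneError(f"{side} margin component is degenerate")
        curves[side] = _oriented(pts, side)
    return curves["left"], curves["right"]


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise EmptySceneError("empty half after midline split")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)
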