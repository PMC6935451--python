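"""End-to-end segmentation pipeline: thermogram in, per-breast masks out.

Wires the stages together in the published order: gray conversion, 3x3
Gaussian denoising, binarization at 0.25, margin extraction, curvature-peak
ellipse initialization, and GVF snake refinement on the denoised gray
image.  The edge map is rescaled to [0, 1] before the GVF computation so
the external-force scale ``kappa`` is independent of image contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import curvature_init, gvf_snake, io_prep
from .curvature_init import EllipseInit, SnakeContour
from .gvf_snake import GVFParams


@dataclass
class SegmentationResult:
    left_mask: np.ndarray
    right_mask: np.ndarray
    left_snake: SnakeContour
    right_snake: SnakeContour
    left_init: EllipseInit
    right_init: EllipseInit
    params: GVFParams


def segment_breasts(
    image: np.ndarray,
    params: GVFParams | None = None,
    threshold: float = 0.25,
    denoise_kernel: int = 3,
    smooth_sigma: float = 3.0,
    min_prominence: float = 0.005,
    contraction: float = 0.95,
    n_vertices: int = 200,
) -> SegmentationResult:
    """Segment the left and right breasts of an RGB thermogram."""
    params = params or GVFParams()
    gray = io_prep.to_gray(image)
    gray = io_prep.denoise(gray, kernel=denoise_kernel)
    mask = io_prep.binarize(gray, threshold=threshold)
    left_curve, right_curve = io_prep.extract_margins(mask, gray)

    em = gvf_snake.edge_map(gray, params=params)
    em = gvf_snake.normalize_edge_map(em)
    fld = gvf_snake.gvf_field(em, mu=params.gvf_mu, n_iter=params.gvf_iterations)
    fld = gvf_snake.normalize_gvf(fld)

    out = {}
    inits = {}
    snakes = {}
    for curve in (left_curve, right_curve):
        ellipse = curvature_init.initial_ellipse_from_curve(
            curve, smooth_sigma=smooth_sigma, min_prominence=min_prominence)
        init = curvature_init.contract_to_snake(
            ellipse, factor=contraction, n_vertices=n_vertices,
            image_shape=gray.shape)
        snake = gvf_snake.evolve_snake(init, fld, params)
        out[curve.side] = gvf_snake.contour_to_mask(snake, gray.shape)
        inits[curve.side] = ellipse
        snakes[curve.side] = snake
    return SegmentationResult(
        left_mask=out["left"], right_mask=out["right"],
        left_snake=snakes["left"], right_snake=snakes["right"],
        left_init=inits["left"], right_init=inits["right"], params=params)
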