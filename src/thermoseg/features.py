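"""Shape, texture and bilateral-asymmetry features of segmented breasts.

Per image the extractor emits a fixed, documented 155-value vector:

* 8 shape values — area A, perimeter P, roundness R = 4*pi*A/P^2 and
  compactness C = A/P^2, for the left and right breast;
* 30 first-order values — mean, median, variance, standard deviation and
  histogram entropy of the in-mask pixels, per RGB channel and side;
* 24 second-order values — GLCM contrast, correlation, energy and local
  homogeneity, per channel and side;
* 93 relation-context values — for each of the 31 paired base features
  (4 shape + 15 first-order + 12 second-order) the Euclidean-style distance
  ED = sqrt((Vr - Vl)^2), the Bhattacharyya-style distance
  BD = sqrt(|Vr * Vl|) and the absolute difference D = |Vr - Vl| between
  the right and left values.

ED and D coincide for scalar pairs; both are kept so the vector honours
the documented 93-value relation block.  BD uses the absolute value of the
product because base features such as GLCM correlation can be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .errors import (
    AssemblyError,
    DegenerateGLCMError,
    EmptyRegionError,
    PairingError,
    ParameterError,
)

CHANNELS = ("R", "G", "B")
SHAPE_NAMES = ("A", "P", "R", "C")
FIRST_ORDER_NAMES = ("mu", "m", "var", "sd", "S")
SECOND_ORDER_NAMES = ("CM", "r", "e", "HL")
RELATION_KINDS = ("ED", "BD", "D")


@dataclass
class ShapeFeatures:
    A: float
    P: float
    R: float
    C: float

    def as_list(self):
        return [self.A, self.P, self.R, self.C]


@dataclass
class FirstOrderFeatures:
    mu: float
    m: float
    var: float
    sd: float
    S: float

    def as_list(self):
        return [self.mu, self.m, self.var, self.sd, self.S]


@dataclass
class GLCM:
    """Normalized gray-level co-occurrence matrix and its marginals."""

    c: np.ndarray
    levels: int
    offset: tuple
    mu_i: float
    mu_j: float
    sigma_i: float
    sigma_j: float


@dataclass
class SecondOrderFeatures:
    CM: float
    r: float
    e: float
    HL: float

    def as_list(self):
        return [self.CM, self.r, self.e, self.HL]


@dataclass
class RelationFeatures:
    ED: np.ndarray
    BD: np.ndarray
    D: np.ndarray


def roundness(area: float, perimeter: float) -> float:
    """R = 4*pi*(A / P^2); equals 1 for a perfect circle."""
    if perimeter <= 0:
        raise ParameterError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def compactness(area: float, perimeter: float, squared: bool = True) -> float:
    """C = A/P^2 (the tabulated form); ``squared=False`` gives the A/P variant."""
    if perimeter <= 0:
        raise ParameterError("perimeter must be positive")
    return area / perimeter**2 if squared else area / perimeter


def region_perimeter(mask: np.ndarray, upsample: int = 4,
                     tolerance: float = 1.0) -> float:
    """Boundary length of the largest foreground region, in pixels.

    The region is treated as a union of unit pixel squares: its outline is
    extracted by marching squares on an ``upsample``-times refined grid and
    simplified with Douglas-Peucker (``tolerance`` in original pixels).
    This reproduces 2(w+h) for a w-by-h rectangle while digitized circles
    approach the smooth circumference as the radius grows.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("cannot measure the perimeter of an empty mask")
    up = np.kron(mask, np.ones((upsample, upsample), dtype=float))
    padded = np.pad(up, 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    simplified = measure.approximate_polygon(contour, tolerance * upsample)
    seg = np.sqrt(np.sum(np.diff(simplified, axis=0) ** 2, axis=1))
    return float(seg.sum()) / upsample


def shape_features(mask: np.ndarray) -> ShapeFeatures:
    """Area, perimeter, roundness and compactness of a segmented region.

    The mask is expected to hold a single connected region; stray extra
    components are ignored in the perimeter (largest outline wins) but
    counted in the area.
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        raise EmptyRegionError("shape features of an empty mask are undefined")
    per = region_perimeter(mask)
    return ShapeFeatures(A=area, P=per, R=roundness(area, per),
                         C=compactness(area, per))


def first_order(img: np.ndarray, mask: np.ndarray, channel: int | str,
                bins: int = 256, entropy_base: float = 2.0) -> FirstOrderFeatures:
    """First-order statistics of the in-mask pixels of one channel.

    The entropy is computed from the normalized ``bins``-bin histogram over
    [0, 1] with the convention 0*log(0) = 0, in bits by default.
    """
    ch = CHANNELS.index(channel) if isinstance(channel, str) else int(channel)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("first-order features of an empty mask")
    v = np.asarray(img, dtype=np.float64)[..., ch][mask]
    mu = float(v.mean())
    med = float(np.median(v))
    var = float(v.var())
    sd = float(np.sqrt(var))
    hist, _ = np.histogram(v, bins=bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p[p > 0]
    entropy = float(-(nz * (np.log(nz) / np.log(entropy_base))).sum())
    return FirstOrderFeatures(mu=mu, m=med, var=var, sd=sd, S=entropy)


def glcm(img: np.ndarray, mask: np.ndarray, channel: int | str,
         levels: int = 8, offset: tuple = (1, 0),
         symmetric: bool = True) -> GLCM:
    """Masked gray-level co-occurrence matrix of one channel.

    The channel is quantized uniformly to ``levels`` bins over [0, 1]; a
    pair is counted when both the pixel and its neighbour at
    ``offset = (dx, dy)`` fall inside the mask.  The matrix is symmetrized
    (by default) and normalized to sum to 1.
    """
    if levels < 2:
        raise ParameterError("GLCM needs at least 2 levels")
    ch = CHANNELS.index(channel) if isinstance(channel, str) else int(channel)
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(img, dtype=np.float64)[..., ch]
    q = np.minimum((vals * levels).astype(int), levels - 1)
    dx, dy = offset
    h, w = mask.shape
    # slice views of (pixel, neighbour) pairs at the offset
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    ys2 = slice(max(0, dy), min(h, h + dy))
    xs2 = slice(max(0, dx), min(w, w + dx))
    valid = mask[ys, xs] & mask[ys2, xs2]
    i = q[ys, xs][valid]
    j = q[ys2, xs2][valid]
    if i.size == 0:
        raise DegenerateGLCMError(
            f"no in-mask pixel pair at offset {offset!r} — region too thin"
        )
    c = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(c, (i, j), 1.0)
    if symmetric:
        c = c + c.T
    c /= c.sum()
    idx = np.arange(levels, dtype=np.float64)
    p_i = c.sum(axis=1)
    p_j = c.sum(axis=0)
    mu_i = float((idx * p_i).sum())
    mu_j = float((idx * p_j).sum())
    sigma_i = float(np.sqrt(((idx - mu_i) ** 2 * p_i).sum()))
    sigma_j = float(np.sqrt(((idx - mu_j) ** 2 * p_j).sum()))
    return GLCM(c=c, levels=levels, offset=(dx, dy), mu_i=mu_i, mu_j=mu_j,
                sigma_i=sigma_i, sigma_j=sigma_j)


def second_order(g: GLCM) -> SecondOrderFeatures:
    """Contrast, correlation, energy and local homogeneity of a GLCM.

    Correlation is defined as 0 when either marginal standard deviation
    vanishes (constant region).
    """
    c = g.c
    i, j = np.meshgrid(np.arange(g.levels), np.arange(g.levels), indexing="ij")
    diff = np.abs(i - j)
    cm = float((diff**2 * c).sum())
    if g.sigma_i > 0 and g.sigma_j > 0:
        r = float((((i - g.mu_i) * (j - g.mu_j) * c).sum())
                  / (g.sigma_i * g.sigma_j))
    else:
        r = 0.0
    e = float((c**2).sum())
    hl = float((c / (1.0 + diff)).sum())
    return SecondOrderFeatures(CM=cm, r=r, e=e, HL=hl)


def relation_features(Vl, Vr) -> RelationFeatures:
    """Per-pair left/right relation distances (bilateral asymmetry).

    ``ED = sqrt((Vr - Vl)^2)``, ``BD = sqrt(|Vr * Vl|)`` and
    ``D = |Vr - Vl|`` for each paired base feature.
    """
    Vl = np.asarray(Vl, dtype=np.float64)
    Vr = np.asarray(Vr, dtype=np.float64)
    if Vl.shape != Vr.shape:
        raise PairingError(
            f"left/right feature lists differ in length: {Vl.shape} vs {Vr.shape}"
        )
    ed = np.sqrt((Vr - Vl) ** 2)
    bd = np.sqrt(np.abs(Vr * Vl))
    d = np.abs(Vr - Vl)
    return RelationFeatures(ED=ed, BD=bd, D=d)


def base_pair_names() -> list:
    """Names of the 31 paired base features, in vector order."""
    names = list(SHAPE_NAMES)
    names += [f"{ch}_{st}" for ch in CHANNELS for st in FIRST_ORDER_NAMES]
    names += [f"{ch}_{st}" for ch in CHANNELS for st in SECOND_ORDER_NAMES]
    return names


def feature_names() -> list:
    """The 155 feature names in their fixed, documented order."""
    names = []
    for side in ("left", "right"):
        names += [f"{side}_{n}" for n in SHAPE_NAMES]
    for side in ("left", "right"):
        names += [f"{side}_{ch}_{st}" for ch in CHANNELS for st in FIRST_ORDER_NAMES]
    for side in ("left", "right"):
        names += [f"{side}_{ch}_{st}" for ch in CHANNELS for st in SECOND_ORDER_NAMES]
    for base in base_pair_names():
        names += [f"rel_{base}_{kind}" for kind in RELATION_KINDS]
    return names


def assemble_vector(left_shape, right_shape, left_first, right_first,
                    left_second, right_second,
                    relations: RelationFeatures) -> pd.Series:
    """Assemble the 155-value feature vector from its blocks.

    ``left_first``/``right_first`` and ``left_second``/``right_second`` are
    mappings from channel name ("R", "G", "B") to the per-channel feature
    objects.  Raises :class:`AssemblyError` naming any missing block.
    """
    blocks = {
        "left shape": left_shape, "right shape": right_shape,
        "left first-order": left_first, "right first-order": right_first,
        "left second-order": left_second, "right second-order": right_second,
        "relations": relations,
    }
    for name, block in blocks.items():
        if block is None:
            raise AssemblyError(f"missing feature block: {name}")
    for name, block in (("first-order", left_first), ("first-order", right_first),
                        ("second-order", left_second), ("second-order", right_second)):
        missing = [ch for ch in CHANNELS if ch not in block]
        if missing:
            raise AssemblyError(f"missing {name} channels: {missing}")
    values = left_shape.as_list() + right_shape.as_list()
    for per_channel in (left_first, right_first):
        for ch in CHANNELS:
            values += per_channel[ch].as_list()
    for per_channel in (left_second, right_second):
        for ch in CHANNELS:
            values += per_channel[ch].as_list()
    rel = np.stack([relations.ED, relations.BD, relations.D], axis=1)
    if rel.shape[0] != len(base_pair_names()):
        raise AssemblyError(
            f"relation block has {rel.shape[0]} pairs, expected "
            f"{len(base_pair_names())}"
        )
    values += rel.reshape(-1).tolist()
    return pd.Series(values, index=feature_names(), dtype=float)


def extract_features(img: np.ndarray, left_mask: np.ndarray,
                     right_mask: np.ndarray, levels: int = 8,
                     offset: tuple = (1, 0)) -> pd.Series:
    """Full 155-value feature vector of one segmented thermogram."""
    lsh = shape_features(left_mask)
    rsh = shape_features(right_mask)
    lfo = {ch: first_order(img, left_mask, ch) for ch in CHANNELS}
    rfo = {ch: first_order(img, right_mask, ch) for ch in CHANNELS}
    lso = {ch: second_order(glcm(img, left_mask, ch, levels, offset))
           for ch in CHANNELS}
    rso = {ch: second_order(glcm(img, right_mask, ch, levels, offset))
           for ch in CHANNELS}
    vl = lsh.as_list()
    vr = rsh.as_list()
    for ch in CHANNELS:
        vl += lfo[ch].as_list()
        vr += rfo[ch].as_list()
    for ch in CHANNELS:
        vl += lso[ch].as_list()
        vr += rso[ch].as_list()
    rel = relation_features(vl, vr)
    return assemble_vector(lsh, rsh, lfo, rfo, lso, rso, rel)
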