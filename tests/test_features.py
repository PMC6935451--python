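"""Shape, first/second-order texture and relation-context features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import draw

from thermoseg import features
from thermoseg.errors import (
    AssemblyError,
    DegenerateGLCMError,
    EmptyRegionError,
    PairingError,
)
from thermoseg.features import GLCM


def _disk_mask(r, pad=5):
    mask = np.zeros((2 * r + 2 * pad, 2 * r + 2 * pad), dtype=bool)
    rr, cc = draw.disk((r + pad, r + pad), r)
    mask[rr, cc] = True
    return mask


class TestShapeFeatures:
    def test_analytic_circle_roundness_is_one(self):
        r = 37.0
        assert features.roundness(np.pi * r**2, 2 * np.pi * r) == \
            pytest.approx(1.0, abs=1e-12)

    def test_square_area(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        assert features.shape_features(mask).A == 100

    def test_rectangle_roundness(self):
        # analytic rectangle oracle: R = 4*pi*A/P^2 with A=100, P=50
        mask = np.zeros((30, 40), dtype=bool)
        mask[10:15, 10:30] = True  # 20 x 5
        got = features.shape_features(mask).R
        expected = 4 * np.pi * 100 / 50.0**2
        assert abs(got - expected) / expected < 0.05

    def test_digitized_circle_roundness_near_one(self):
        shape = features.shape_features(_disk_mask(40))
        assert 0.9 < shape.R <= 1.0 + 0.05

    def test_compactness_table_form(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        shape = features.shape_features(mask)
        assert shape.C == pytest.approx(shape.A / shape.P**2)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            features.shape_features(np.zeros((5, 5), dtype=bool))


def _rgb_from_channel(vals):
    """(H, W) values -> RGB image with that channel everywhere."""
    return np.repeat(np.asarray(vals, dtype=float)[:, :, None], 3, axis=2)


class TestFirstOrder:
    def test_constant_region(self):
        img = _rgb_from_channel(np.full((6, 6), 0.3))
        fo = features.first_order(img, np.ones((6, 6), bool), "R")
        assert fo.mu == pytest.approx(0.3)
        assert fo.var == pytest.approx(0.0, abs=1e-15)
        assert fo.sd == pytest.approx(0.0, abs=1e-7)
        assert fo.S == 0

    def test_two_point_uniform(self):
        vals = np.zeros((2, 4))
        vals[:, 2:] = 1.0
        fo = features.first_order(_rgb_from_channel(vals),
                                  np.ones((2, 4), bool), "G")
        assert fo.mu == pytest.approx(0.5)
        assert fo.S == pytest.approx(1.0)  # one bit

    def test_hand_computed_moments(self):
        vals = np.array([[0.1, 0.2, 0.3, 0.4]])
        fo = features.first_order(_rgb_from_channel(vals),
                                  np.ones((1, 4), bool), "B")
        assert fo.mu == pytest.approx(0.25)
        assert fo.var == pytest.approx(0.0125)  # population variance
        assert fo.sd == pytest.approx(np.sqrt(0.0125))
        assert fo.m == pytest.approx(0.25)

    def test_entropy_increases_under_flattening(self):
        concentrated = np.full((4, 8), 0.5)
        concentrated[0, 0] = 0.6
        flat = np.linspace(0, 0.99, 32).reshape(4, 8)
        mask = np.ones((4, 8), bool)
        s_conc = features.first_order(_rgb_from_channel(concentrated), mask, 0).S
        s_flat = features.first_order(_rgb_from_channel(flat), mask, 0).S
        assert s_flat > s_conc

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRegionError):
            features.first_order(np.zeros((3, 3, 3)), np.zeros((3, 3), bool), 0)


class TestGLCM:
    def test_constant_region_single_entry(self):
        img = _rgb_from_channel(np.full((5, 5), 0.4))
        g = features.glcm(img, np.ones((5, 5), bool), "R", levels=8)
        assert g.c.sum() == pytest.approx(1.0)
        assert np.count_nonzero(g.c) == 1
        assert g.c[3, 3] == pytest.approx(1.0)  # 0.4 quantized to bin 3 of 8

    def test_vertical_stripes(self):
        vals = np.zeros((6, 6))
        vals[:, 1::2] = 0.9
        g = features.glcm(_rgb_from_channel(vals), np.ones((6, 6), bool),
                          "G", levels=2, offset=(1, 0))
        assert g.c[0, 1] == pytest.approx(0.5)
        assert g.c[1, 0] == pytest.approx(0.5)

    def test_toy_block_matches_pair_enumeration(self):
        # brute-force pair-count oracle on a printed 4x4 block
        block = np.array([[0.0, 0.1, 0.3, 0.3],
                          [0.1, 0.2, 0.6, 0.8],
                          [0.4, 0.4, 0.5, 0.9],
                          [0.7, 0.7, 0.1, 0.2]])
        levels = 4
        q = np.minimum((block * levels).astype(int), levels - 1)
        expected = np.zeros((levels, levels))
        for y in range(4):
            for x in range(3):  # offset (1, 0)
                expected[q[y, x], q[y, x + 1]] += 1
        expected = expected + expected.T
        expected /= expected.sum()
        g = features.glcm(_rgb_from_channel(block), np.ones((4, 4), bool),
                          0, levels=4, offset=(1, 0))
        np.testing.assert_allclose(g.c, expected, atol=1e-12)

    def test_against_skimage_on_full_rectangle(self):
        # independent library oracle (no mask support there, so full mask)
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(5)
        vals = rng.random((12, 10))
        levels = 8
        g = features.glcm(_rgb_from_channel(vals), np.ones((12, 10), bool),
                          0, levels=levels, offset=(1, 0))
        q = np.minimum((vals * levels).astype(np.uint8), levels - 1)
        ref = graycomatrix(q, [1], [0], levels=levels, symmetric=True,
                           normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(g.c, ref, atol=1e-12)

    def test_thin_mask_degenerate(self):
        mask = np.zeros((5, 5), bool)
        mask[:, 2] = True  # single column; horizontal pairs impossible
        with pytest.raises(DegenerateGLCMError):
            features.glcm(np.zeros((5, 5, 3)), mask, 0, offset=(1, 0))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_normalization_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((8, 8))
        mask = rng.random((8, 8)) > 0.3
        mask[:2, :2] = True  # guarantee at least one pair
        g = features.glcm(_rgb_from_channel(vals), mask, 0, levels=6)
        assert g.c.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(g.c, g.c.T, atol=1e-12)
        assert (g.c >= 0).all()


def _uniform_glcm(levels, entries):
    c = np.zeros((levels, levels))
    for i, j in entries:
        c[i, j] = 1.0
    c /= c.sum()
    idx = np.arange(levels, dtype=float)
    p_i, p_j = c.sum(1), c.sum(0)
    mu_i, mu_j = (idx * p_i).sum(), (idx * p_j).sum()
    return GLCM(c=c, levels=levels, offset=(1, 0), mu_i=mu_i, mu_j=mu_j,
                sigma_i=np.sqrt(((idx - mu_i) ** 2 * p_i).sum()),
                sigma_j=np.sqrt(((idx - mu_j) ** 2 * p_j).sum()))


class TestSecondOrder:
    def test_constant_region_glcm(self):
        so = features.second_order(_uniform_glcm(4, [(2, 2)]))
        assert so.CM == 0 and so.e == 1 and so.HL == 1 and so.r == 0

    def test_identity_diagonal(self):
        so = features.second_order(
            _uniform_glcm(4, [(i, i) for i in range(4)]))
        assert so.CM == 0
        assert so.e == pytest.approx(0.25)
        assert so.r == pytest.approx(1.0)

    def test_hand_evaluated_two_by_two(self):
        g = _uniform_glcm(2, [(0, 0), (0, 1), (1, 0), (1, 1)])
        so = features.second_order(g)
        assert so.CM == pytest.approx(0.5)
        assert so.e == pytest.approx(0.25)
        assert so.HL == pytest.approx(0.75)
        assert so.r == pytest.approx(0.0)


class TestRelationFeatures:
    def test_symmetric_input_zero_distances(self):
        v = [1.0, 2.5, -3.0]
        rel = features.relation_features(v, v)
        np.testing.assert_array_equal(rel.ED, 0.0)
        np.testing.assert_array_equal(rel.D, 0.0)

    def test_hand_evaluated_pair(self):
        rel = features.relation_features([1.0], [3.0])
        assert rel.ED[0] == pytest.approx(2.0)
        assert rel.D[0] == pytest.approx(2.0)
        assert rel.BD[0] == pytest.approx(np.sqrt(3.0))

    def test_zero_product(self):
        assert features.relation_features([0.0], [0.0]).BD[0] == 0.0

    def test_negative_product_stays_real(self):
        rel = features.relation_features([-0.5], [0.5])
        assert rel.BD[0] == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            features.relation_features([1.0, 2.0], [1.0])


class TestAssembly:
    def test_block_count_identities(self):
        names = features.feature_names()
        assert len(names) == 155
        rel = [n for n in names if n.startswith("rel_")]
        assert len(rel) == 93
        assert len(features.base_pair_names()) == 31  # 4 + 15 + 12
        assert 8 + 30 + 24 + 93 == 155
        assert len(set(names)) == 155  # unique, stable naming

    def test_full_vector_on_phantom(self, normal_phantom):
        vec = features.extract_features(normal_phantom.image,
                                        normal_phantom.left_mask,
                                        normal_phantom.right_mask)
        assert len(vec) == 155
        assert np.isfinite(vec.to_numpy()).all()

    def test_identical_sides_zero_relations(self, normal_phantom):
        vec = features.extract_features(normal_phantom.image,
                                        normal_phantom.left_mask,
                                        normal_phantom.left_mask)
        rel_ed = vec[[n for n in vec.index if n.endswith("_ED")]]
        rel_d = vec[[n for n in vec.index if n.endswith("_D")
                     and not n.endswith("_ED")]]
        np.testing.assert_array_equal(rel_ed.to_numpy(), 0.0)
        np.testing.assert_array_equal(rel_d.to_numpy(), 0.0)

    def test_missing_block_named(self, normal_phantom):
        lsh = features.shape_features(normal_phantom.left_mask)
        with pytest.raises(AssemblyError, match="right shape"):
            features.assemble_vector(lsh, None, {}, {}, {}, {},
                                     features.relation_features([], []))

    def test_translation_invariance(self, normal_phantom):
        img = normal_phantom.image
        lm, rm = normal_phantom.left_mask, normal_phantom.right_mask
        v1 = features.extract_features(img, lm, rm)
        shift = (7, 5)
        img2 = np.roll(img, shift, axis=(0, 1))
        lm2 = np.roll(lm, shift, axis=(0, 1))
        rm2 = np.roll(rm, shift, axis=(0, 1))
        v2 = features.extract_features(img2, lm2, rm2)
        np.testing.assert_allclose(v1.to_numpy(), v2.to_numpy(), atol=1e-9)
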