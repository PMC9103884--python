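"""Co-occurrence and run-length matrices against brute-force enumeration."""

import numpy as np
import pytest

from texconcord.features.glcm import (
    DIRECTIONS_2D,
    DIRECTIONS_3D,
    glcm,
    glcm_features,
)
from texconcord.features.rlm import rlm_features, run_length_matrix
from texconcord.roi import QuantizedROI, quantize_roi

from .oracles import glcm_bruteforce, haralick_bruteforce, rlm_bruteforce


def quantized(levels, ng):
    levels = np.asarray(levels)
    return QuantizedROI(levels, levels >= 0, ng, (0.0, float(ng)))


class TestGlcmMatrix:
    def test_constant_roi_single_cell(self):
        q = quantized(np.zeros((6, 6), int), 4)
        for d in DIRECTIONS_2D:
            m = glcm(q, d, 1)
            assert m.probabilities[0, 0] == 1.0
            assert m.probabilities.sum() == pytest.approx(1.0)

    def test_horizontal_stripes_vertical_direction(self):
        # alternating single-pixel-high stripes: vertically adjacent pixels
        # always differ by one level
        levels = np.zeros((6, 6), int)
        levels[1::2] = 1
        m = glcm(quantized(levels, 2), "90", 1)
        assert m.probabilities[0, 1] + m.probabilities[1, 0] == pytest.approx(1.0)
        assert m.probabilities[0, 0] == 0.0 and m.probabilities[1, 1] == 0.0

    @pytest.mark.parametrize("direction", list(DIRECTIONS_2D))
    @pytest.mark.parametrize("distance", [1, 2, 3, 4, 5])
    def test_matches_pair_enumeration(self, direction, distance, rng):
        levels = rng.integers(0, 6, (8, 8))
        mask = rng.random((8, 8)) > 0.2
        levels[~mask] = -1
        q = QuantizedROI(levels, mask, 6, (0.0, 6.0))
        unit = DIRECTIONS_2D[direction]
        offset = tuple(distance * o for o in unit)
        expected = glcm_bruteforce(levels, mask, offset, 6)
        if expected.sum() == 0:
            with pytest.raises(ValueError, match=direction):
                glcm(q, direction, distance)
            return
        got = glcm(q, direction, distance).probabilities
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_3d_offsets_match_enumeration(self, rng):
        levels = rng.integers(0, 4, (4, 6, 6))
        mask = np.ones((4, 6, 6), bool)
        levels_masked = levels.copy()
        q = QuantizedROI(levels_masked, mask, 4, (0.0, 4.0))
        for name, unit in DIRECTIONS_3D.items():
            expected = glcm_bruteforce(levels, mask, unit, 4)
            got = glcm(q, name, 1).probabilities
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_too_thin_mask_errors_with_context(self):
        levels = np.zeros((1, 8), int)
        q = QuantizedROI(levels, np.ones((1, 8), bool), 2, (0.0, 2.0))
        with pytest.raises(ValueError, match="90.*distance 1|direction 90"):
            glcm(q, "90", 1)


class TestGlcmFeatures:
    def test_constant_matrix_degenerate_values(self):
        q = quantized(np.zeros((6, 6), int), 4)
        f = glcm_features(glcm(q, "0", 1))
        assert f["asm"] == pytest.approx(1.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["entropy"] == pytest.approx(0.0)

    def test_checkerboard_contrast_one(self):
        levels = (np.indices((8, 8)).sum(axis=0) % 2).astype(int)
        f = glcm_features(glcm(quantized(levels, 2), "0", 1))
        assert f["contrast"] == pytest.approx(1.0)

    def test_correlation_limit_diagonal(self):
        # mass only on the diagonal with spread marginals: ρ -> 1
        p = np.zeros((4, 4))
        p[np.arange(4), np.arange(4)] = 0.25
        from texconcord.features.glcm import CooccurrenceMatrix

        f = glcm_features(CooccurrenceMatrix(p, "0", 1, 100))
        assert f["correlation"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_definition_sums(self, rng):
        for _ in range(10):
            levels = rng.integers(0, 5, (10, 10))
            q = quantized(levels, 5)
            m = glcm(q, "45", 2)
            got = glcm_features(m)
            expected = haralick_bruteforce(m.probabilities)
            for k, v in expected.items():
                assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_unnormalized_matrix_rejected(self):
        from texconcord.features.glcm import CooccurrenceMatrix

        with pytest.raises(ValueError):
            CooccurrenceMatrix(np.ones((3, 3)), "0", 1, 9)


class TestRunLength:
    def test_single_run_closed_form(self):
        levels = np.zeros((1, 7), int)
        q = QuantizedROI(levels, np.ones((1, 7), bool), 2, (0.0, 2.0))
        f = rlm_features(q, "0")
        assert f["long_run_emphasis"] == pytest.approx(49.0)
        assert f["short_run_emphasis"] == pytest.approx(1.0 / 49.0)
        assert f["run_percentage"] == pytest.approx(1.0 / 7.0)

    def test_alternating_row_all_length_one(self):
        levels = np.array([[0, 1] * 5])
        q = QuantizedROI(levels, np.ones((1, 10), bool), 2, (0.0, 2.0))
        f = rlm_features(q, "0")
        assert f["short_run_emphasis"] == pytest.approx(1.0)
        assert f["run_percentage"] == pytest.approx(1.0)

    def test_run_weighted_pixel_conservation(self, rng):
        levels = rng.integers(0, 3, (9, 9))
        mask = rng.random((9, 9)) > 0.25
        levels[~mask] = -1
        q = QuantizedROI(levels, mask, 3, (0.0, 3.0))
        rlm = run_length_matrix(q, "135")
        lengths = np.arange(1, rlm.counts.shape[1] + 1)
        assert (rlm.counts.sum(axis=0) * lengths).sum() == mask.sum()

    @pytest.mark.parametrize("direction", list(DIRECTIONS_2D))
    def test_matches_line_scanner(self, direction, rng):
        for _ in range(15):
            levels = rng.integers(0, 4, (10, 10))
            mask = rng.random((10, 10)) > 0.2
            levels[~mask] = -1
            q = QuantizedROI(levels, mask, 4, (0.0, 4.0))
            if not mask.any():
                continue
            got = run_length_matrix(q, direction).counts
            expected = rlm_bruteforce(levels, mask, DIRECTIONS_2D[direction], 4)
            w = max(got.shape[1], expected.shape[1])
            g = np.zeros((4, w), int)
            e = np.zeros((4, w), int)
            g[:, : got.shape[1]] = got
            e[:, : expected.shape[1]] = expected
            np.testing.assert_array_equal(g, e)

    def test_3d_directions_match_line_scanner(self, rng):
        from texconcord.features.glcm import DIRECTIONS_3D

        levels = rng.integers(0, 3, (4, 5, 5))
        mask = rng.random((4, 5, 5)) > 0.15
        levels[~mask] = -1
        q = QuantizedROI(levels, mask, 3, (0.0, 3.0))
        for name, unit in DIRECTIONS_3D.items():
            got = run_length_matrix(q, name).counts
            expected = rlm_bruteforce(levels, mask, unit, 3)
            w = max(got.shape[1], expected.shape[1])
            g = np.zeros((3, w), int)
            e = np.zeros((3, w), int)
            g[:, : got.shape[1]] = got
            e[:, : expected.shape[1]] = expected
            np.testing.assert_array_equal(g, e)

    def test_empty_roi_rejected(self):
        q = QuantizedROI(np.full((4, 4), -1), np.zeros((4, 4), bool), 2, (0, 1))
        with pytest.raises(ValueError, match="empty"):
            run_length_matrix(q, "0")
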