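"""GLCM, GLDS and Haar texture descriptors against brute-force oracles."""

import numpy as np
import pytest

from echodose import (
    GLCMatrix,
    GLDSHistogram,
    extract_B_features,
    glcm,
    glcm_features,
    glds,
    glds_features,
    haar_features,
    quantize,
    simulate_speckle_background,
    SpeckleParams,
)

# ---------------------------------------------------------------------------
# independent oracles (literal double loops / formula transcriptions)


def glcm_oracle(raster, offsets, levels):
    """O(N * |offsets|) pair enumeration, symmetrized and normalized."""
    counts = np.zeros((levels, levels))
    rows, cols = raster.shape
    for dr, dc in offsets:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[raster[r, c], raster[r2, c2]] += 1
                    counts[raster[r2, c2], raster[r, c]] += 1
    return counts / counts.sum()


def glcm_features_oracle(p):
    """Literal transcription of the six Haralick formulas."""
    L = p.shape[0]
    contrast = sum(
        (i - j) ** 2 * p[i, j] for i in range(L) for j in range(L)
    )
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    psum = np.zeros(2 * L - 1)
    pdiff = np.zeros(2 * L - 1)
    for i in range(L):
        for j in range(L):
            psum[i + j] += p[i, j]
            pdiff[i - j + L - 1] += p[i, j]
    sum_avg = sum(k * psum[k] for k in range(2 * L - 1))
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sos = sum((i - mu_x) ** 2 * p[i, j] for i in range(L) for j in range(L))
    kd = np.arange(2 * L - 1) - (L - 1)
    mu_d = float(kd @ pdiff)
    dvar = float((kd - mu_d) ** 2 @ pdiff)
    sx = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sy = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))
    if sx * sy > 0:
        corr = (
            sum(i * j * p[i, j] for i in range(L) for j in range(L)) - mu_x * mu_y
        ) / (sx * sy)
    else:
        corr = 0.0
    return {
        "B_GLCM_Contrast": contrast,
        "B_GLCM_SumAverage": sum_avg,
        "B_GLCM_SoSVariance": sos,
        "B_GLCM_DVariance": dvar,
        "B_GLCM_Correlation": corr,
        "B_GLCM_IDMoment": idm,
    }


# ---------------------------------------------------------------------------


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


rasters = arrays(
    np.uint8, st.tuples(st.integers(2, 12), st.integers(2, 12)),
    elements=st.integers(0, 255),
)


class TestProperties:
    @settings(max_examples=50, derandomize=True)
    @given(raster=rasters, levels=st.integers(2, 64))
    def test_quantize_range_and_monotonicity(self, raster, levels):
        q = quantize(raster, levels)
        assert q.min() >= 0 and q.max() <= levels - 1
        order = np.argsort(raster.ravel())
        assert np.all(np.diff(q.ravel()[order].astype(int)) >= 0)

    @settings(max_examples=50, derandomize=True)
    @given(raster=rasters)
    def test_glcm_is_a_symmetric_distribution(self, raster):
        m = glcm(quantize(raster, 16), levels=16)
        assert abs(m.p.sum() - 1.0) < 1e-9
        assert np.allclose(m.p, m.p.T, atol=1e-9)
        assert np.all(m.p >= 0)

    @settings(max_examples=50, derandomize=True)
    @given(raster=rasters)
    def test_glds_is_a_distribution(self, raster):
        if raster.shape[1] < 2:
            return
        h = glds(quantize(raster, 16), (0, 1), levels=16)
        assert abs(h.g.sum() - 1.0) < 1e-9
        assert np.all(h.g >= 0)


class TestQuantize:
    def test_constant_frame_single_level(self):
        q = quantize(np.full((8, 8), 131, dtype=np.uint8), 32)
        assert np.unique(q).tolist() == [131 * 32 // 256]

    def test_full_ramp_is_surjective(self):
        ramp = np.arange(256, dtype=np.uint8).reshape(16, 16)
        q = quantize(ramp, 32)
        assert sorted(np.unique(q)) == list(range(32))

    def test_monotone(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 256, size=200)
        b = rng.integers(0, 256, size=200)
        qa, qb = quantize(a, 32), quantize(b, 32)
        assert np.all((a >= b) | (qa <= qb))

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((4, 4), dtype=np.uint8), 1)


class TestGLCM:
    def test_two_column_raster(self):
        m = glcm(np.array([[0, 1], [0, 1]], dtype=np.uint8), offsets=((0, 1),), levels=2)
        assert np.allclose(m.p, [[0, 0.5], [0.5, 0]])

    def test_constant_raster_single_cell(self):
        m = glcm(np.full((5, 5), 3, dtype=np.uint8), levels=8)
        assert np.isclose(m.p[3, 3], 1.0)
        assert np.isclose(m.p.sum(), 1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        offsets = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
        for _ in range(50):
            raster = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
            m = glcm(raster, offsets=offsets, levels=8)
            assert np.allclose(m.p, glcm_oracle(raster, offsets, 8), atol=1e-12)

    def test_normalized_and_symmetric(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            raster = rng.integers(0, 16, size=(12, 20)).astype(np.uint8)
            m = glcm(raster, levels=16)
            assert abs(m.p.sum() - 1.0) < 1e-9
            assert np.allclose(m.p, m.p.T, atol=1e-9)

    def test_all_offsets_outside_raster_rejected(self):
        with pytest.raises(ValueError):
            glcm(np.zeros((2, 2), dtype=np.uint8), offsets=((5, 5),), levels=2)


class TestGLCMFeatures:
    def test_checkerboard_matrix_closed_form(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(GLCMatrix(p=p, levels=2, offsets=((0, 1),)))
        assert np.isclose(f["B_GLCM_Contrast"], 1.0)
        assert np.isclose(f["B_GLCM_IDMoment"], 0.5)
        assert np.isclose(f["B_GLCM_Correlation"], -1.0)
        assert np.isclose(f["B_GLCM_SumAverage"], 1.0)

    def test_constant_matrix_degenerate(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = glcm_features(GLCMatrix(p=p, levels=4, offsets=((0, 1),)))
        assert f["B_GLCM_Contrast"] == 0.0
        assert f["B_GLCM_IDMoment"] == 1.0
        assert f["B_GLCM_Correlation"] == 0.0

    def test_matches_formula_oracle_on_random_matrices(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            L = int(rng.integers(2, 9))
            raw = rng.random((L, L))
            raw = raw + raw.T
            p = raw / raw.sum()
            mine = glcm_features(GLCMatrix(p=p, levels=L, offsets=((0, 1),)))
            oracle = glcm_features_oracle(p)
            for k in mine:
                assert np.isclose(mine[k], oracle[k], atol=1e-9), k

    def test_contrast_invariant_under_gray_level_inversion(self):
        rng = np.random.default_rng(10)
        raster = rng.integers(0, 8, size=(16, 16)).astype(np.uint8)
        f1 = glcm_features(glcm(raster, levels=8))
        f2 = glcm_features(glcm((7 - raster).astype(np.uint8), levels=8))
        assert np.isclose(f1["B_GLCM_Contrast"], f2["B_GLCM_Contrast"], atol=1e-12)


class TestGLDS:
    def test_constant_raster(self):
        h = glds(np.full((4, 4), 5, dtype=np.uint8), (0, 1), levels=8)
        assert h.g[0] == 1.0

    def test_two_column_raster(self):
        h = glds(np.array([[0, 1], [0, 1]], dtype=np.uint8), (0, 1), levels=2)
        assert np.allclose(h.g, [0.0, 1.0])

    def test_normalization_on_random_rasters(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            raster = rng.integers(0, 32, size=(10, 14)).astype(np.uint8)
            for delta in ((0, 1), (1, 0), (1, 1), (0, 2)):
                assert np.isclose(glds(raster, delta, levels=32).g.sum(), 1.0)

    def test_matches_brute_force_histogram(self):
        rng = np.random.default_rng(12)
        raster = rng.integers(0, 6, size=(9, 9)).astype(np.uint8)
        h = glds(raster, (1, 1), levels=6)
        counts = np.zeros(6)
        for r in range(8):
            for c in range(8):
                counts[abs(int(raster[r, c]) - int(raster[r + 1, c + 1]))] += 1
        assert np.allclose(h.g, counts / counts.sum(), atol=1e-12)

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            glds(np.zeros((4, 4), dtype=np.uint8), (0, 0))

    def test_oversized_displacement_rejected(self):
        with pytest.raises(ValueError):
            glds(np.zeros((4, 4), dtype=np.uint8), (0, 9))


class TestGLDSFeatures:
    @pytest.mark.parametrize(
        "g,expected",
        [
            ([1, 0], dict(mean=0, contrast=0, asm=1, entropy=0, hom=1)),
            ([0, 1], dict(mean=1, contrast=1, asm=1, entropy=0, hom=0.5)),
        ],
    )
    def test_point_mass_histograms(self, g, expected):
        f = glds_features(GLDSHistogram(g=np.array(g, float), displacement=(0, 1)))
        assert np.isclose(f["B_GLDS_Mean"], expected["mean"])
        assert np.isclose(f["B_GLDS_Contrast"], expected["contrast"])
        assert np.isclose(f["B_GLDS_ASM"], expected["asm"])
        assert np.isclose(f["B_GLDS_Entropy"], expected["entropy"])
        assert np.isclose(f["B_GLDS_Homogeneity"], expected["hom"])

    def test_uniform_entropy_closed_form(self):
        f = glds_features(GLDSHistogram(g=np.full(4, 0.25), displacement=(0, 1)))
        assert np.isclose(f["B_GLDS_Entropy"], np.log(4))

    def test_uniform_maximizes_entropy_for_fixed_support(self):
        rng = np.random.default_rng(13)
        uniform = glds_features(GLDSHistogram(g=np.full(8, 1 / 8), displacement=(0, 1)))
        for _ in range(50):
            g = rng.random(8)
            g /= g.sum()
            f = glds_features(GLDSHistogram(g=g, displacement=(0, 1)))
            assert f["B_GLDS_Entropy"] <= uniform["B_GLDS_Entropy"] + 1e-12


class TestHaar:
    def test_constant_frame_zero_details(self):
        assert haar_features(np.full((8, 8), 77.0)) == (0.0, 0.0)

    def test_dc_invariance(self):
        rng = np.random.default_rng(14)
        frame = rng.random((16, 16)) * 200
        assert np.allclose(haar_features(frame), haar_features(frame + 30.0))

    def test_step_edge_mean_scales_linearly(self):
        """A vertical step of height h yields detail statistics linear in h."""
        def step(h):
            # step placed mid-pair: a step on the dyadic grid has zero detail
            f = np.zeros((16, 16))
            f[:, 7:] = h
            return haar_features(f)[0]

        m1, m2 = step(10.0), step(20.0)
        assert m1 > 0
        assert np.isclose(m2, 2 * m1)

    def test_odd_edges_cropped(self):
        rng = np.random.default_rng(15)
        f = rng.random((17, 17))
        assert np.allclose(haar_features(f), haar_features(f[:16, :16]))


class TestExtractBFeatures:
    def test_constant_roi_degenerate(self):
        frame = np.full((32, 32), 90, dtype=np.uint8)
        b = extract_B_features(frame)
        assert b.B_GLCM_Contrast == 0.0
        assert b.B_GLCM_IDMoment == 1.0
        assert b.B_GLDS_ASM == 1.0
        assert b.B_haar_mean == b.B_haar_variance == 0.0

    def test_deterministic_and_finite_on_speckle(self):
        for seed in range(10):
            f = simulate_speckle_background(
                SpeckleParams(image_height=64, image_width=64, seed=seed)
            )
            b1 = extract_B_features(f)
            b2 = extract_B_features(f)
            assert b1 == b2
            assert all(np.isfinite(v) for v in b1.as_dict().values())
            assert -1.0 <= b1.B_GLCM_Correlation <= 1.0
            assert 0.0 < b1.B_GLCM_IDMoment <= 1.0
            assert 0.0 < b1.B_GLDS_ASM <= 1.0
            assert b1.B_GLDS_Entropy >= 0.0
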