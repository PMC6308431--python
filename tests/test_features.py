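import numpy as np
import pytest

from blastograde import features as feat, synthetic


def brute_force_glcm(img, mask, dr, dc, levels=8):
    """All-pairs enumeration oracle for the masked symmetric GLCM."""
    q = np.minimum(img.astype(int) * levels // 256, levels - 1)
    m = np.zeros((levels, levels))
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                m[q[r, c], q[r2, c2]] += 1
                m[q[r2, c2], q[r, c]] += 1
    return m


class TestGlcmCompute:
    def test_two_by_two_horizontal_pairs(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        g = feat.glcm_compute(img, angle=0, levels=2)
        np.testing.assert_array_equal(g.matrix, [[2, 0], [0, 2]])

    def test_two_by_two_vertical_pairs(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        g = feat.glcm_compute(img, angle=90, levels=2)
        np.testing.assert_array_equal(g.matrix, [[0, 2], [2, 0]])

    def test_constant_region_diagonal_mass(self):
        img = np.full((6, 6), 100, dtype=np.uint8)
        g = feat.glcm_compute(img, angle=45).normalize()
        level = feat.quantize(np.array([100]))[0]
        assert g.matrix[level, level] == pytest.approx(1.0)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_matches_brute_force_enumeration(self, angle):
        offs = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
        dr, dc = offs[angle]
        for s in range(20):
            rng = np.random.default_rng(s)
            img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
            mask = rng.random((8, 8)) > 0.3
            if mask.sum() < 2:
                continue
            g = feat.glcm_compute(img, mask, angle=angle)
            np.testing.assert_array_equal(g.matrix, brute_force_glcm(img, mask, dr, dc))

    def test_empty_region_rejected(self):
        with pytest.raises(feat.EmptyRegionError):
            feat.glcm_compute(np.zeros((4, 4), np.uint8), np.zeros((4, 4), bool))


class TestGlcmStats:
    def _normalized(self, matrix):
        g = feat.GLCM(matrix=np.asarray(matrix, float), distance=1, angle=0,
                      levels=len(matrix))
        return g.normalize()

    def test_uniform_two_level(self):
        s = feat.glcm_stats(self._normalized(np.ones((2, 2))))
        assert s["energy"] == pytest.approx(0.25)
        assert s["entropy"] == pytest.approx(2.0)

    def test_degenerate_single_cell(self):
        m = np.zeros((4, 4))
        m[0, 0] = 8
        s = feat.glcm_stats(self._normalized(m))
        assert s["contrast"] == 0 and s["energy"] == 1 and s["entropy"] == 0

    def test_diagonal_mass_homogeneity_one(self):
        s = feat.glcm_stats(self._normalized(np.diag([1, 2, 3, 4])))
        assert s["contrast"] == 0
        assert s["homogeneity"] == pytest.approx(1.0)

    def test_requires_normalized(self):
        g = feat.GLCM(matrix=np.ones((2, 2)), distance=1, angle=0, levels=2)
        with pytest.raises(ValueError):
            feat.glcm_stats(g)

    def test_stat_ranges_on_random_glcms(self):
        for s in range(10):
            rng = np.random.default_rng(s)
            m = rng.random((8, 8))
            stats = feat.glcm_stats(self._normalized(m + m.T))
            assert 0 <= stats["entropy"] <= 2 * np.log2(8)
            assert 0 < stats["energy"] <= 1
            assert 0 < stats["homogeneity"] <= 1


class TestExtractFeatures:
    def test_vector_schema(self, microscope_segmentation):
        s, _ = microscope_segmentation
        fv = feat.extract_features(s)
        assert len(fv.values) == 36
        assert fv.names == feat.FEATURE_NAMES
        assert np.isfinite(fv.values).all()

    def test_er_radius_field(self, microscope_segmentation):
        s, _ = microscope_segmentation
        fv = feat.extract_features(s).as_dict()
        assert fv["er_radius"] == s.circle.radius + 5
        assert fv["rr_radius"] == s.circle.radius - 40

    def test_deterministic(self, microscope_segmentation):
        s, _ = microscope_segmentation
        a = feat.extract_features(s).values
        b = feat.extract_features(s).values
        np.testing.assert_array_equal(a, b)

    def test_unsegmented_rejected(self):
        from blastograde.segmentation import SegmentationResult
        with pytest.raises(feat.ExtractionError):
            feat.extract_features(SegmentationResult(circle=None, status="none"))


class TestVif:
    def test_orthogonal_columns_vif_one(self):
        n = 200
        x = np.zeros((n, 2))
        x[:, 0] = np.sin(np.arange(n))
        x[:, 1] = np.cos(np.arange(n) * 2)
        assert feat.vif(x, 0) == pytest.approx(1.0, abs=0.05)

    def test_exact_collinearity_infinite(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 100))
        x = np.column_stack([a, b, a + b])
        assert np.isinf(feat.vif(x, 2))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(300, 3))
        chol = np.linalg.cholesky(0.9 * np.ones((3, 3)) + 0.1 * np.eye(3))
        x = z @ chol.T
        for col in range(3):
            y = x[:, col]
            design = np.column_stack([np.ones(300), np.delete(x, col, axis=1)])
            beta = np.linalg.solve(design.T @ design, design.T @ y)
            ss_res = ((y - design @ beta) ** 2).sum()
            ss_tot = ((y - y.mean()) ** 2).sum()
            expected = 1.0 / (1.0 - (1 - ss_res / ss_tot))
            assert feat.vif(x, col) == pytest.approx(expected, rel=1e-8)

    def test_matches_inverse_correlation_diagonal(self):
        """Independent oracle: VIF_k = [R^-1]_kk for standardized columns."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(250, 6))
        x[:, 3] += 0.8 * x[:, 0]
        corr = np.corrcoef(x, rowvar=False)
        diag = np.diag(np.linalg.inv(corr))
        for col in range(6):
            assert feat.vif(x, col) == pytest.approx(diag[col], rel=1e-6)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.outliers_influence")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 5))
        x[:, 4] += x[:, 1] * 0.7
        design = np.column_stack([np.ones(200), x])
        for col in range(5):
            expected = statsmodels.variance_inflation_factor(design, col + 1)
            assert feat.vif(x, col) == pytest.approx(expected, rel=1e-6)


class TestVifPrune:
    def test_independent_noise_no_removals(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(300, 10))
        kept, report = feat.vif_prune(x, names=[f"c{i}" for i in range(10)])
        assert len(kept) == 10
        assert report.removed == []
        assert max(report.final_vifs.values()) <= 10

    def test_constructed_duplicates_all_removed(self):
        x, y = synthetic.generate_feature_dataset(50, separation=6.0, seed=5)
        x36, names = synthetic.extend_with_collinear(x, seed=5)
        kept, report = feat.vif_prune(x36, names=names)
        assert len(kept) == 24
        assert sorted(kept) == sorted(n for n in names if not n.startswith("dup"))
        assert len(report.iterations) == 13  # 12 removals + confirmation pass
        assert max(report.final_vifs.values()) <= 10

    def test_tie_removes_earlier_column(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=120)
        b = rng.normal(size=120)
        x = np.column_stack([a, a.copy(), b])  # identical pair -> inf VIF tie
        kept, report = feat.vif_prune(x, names=["first", "second", "other"])
        assert report.removed == ["first"]
        assert kept == ["second", "other"]

    def test_too_few_rows_rejected(self):
        with pytest.raises(feat.IllPosedError):
            feat.vif_prune(np.random.default_rng(7).normal(size=(10, 12)))
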