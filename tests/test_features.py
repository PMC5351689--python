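"""Texture and conventional feature extraction against hand-derived values
and brute-force enumeration oracles."""

import numpy as np
import pytest
from conftest import make_suv_phantom, random_levels
from oracles import (
    glcm_features_oracle,
    glcm_oracle,
    glszm_features_oracle,
    glszm_oracle,
)

import sstrtex as sx
from sstrtex.errors import DegenerateTextureError, FeatureError
from sstrtex.features import (
    FEATURE_COLUMNS,
    DiscretizedLesion,
    ExtractionConfig,
    FeatureVector,
    GLCMatrix,
    LesionExclusion,
    default_offsets,
)


def _dlesion(levels, ng):
    levels = np.asarray(levels, dtype=np.int32)
    return DiscretizedLesion(levels=levels, n_levels=ng, bin_edges=np.linspace(0, 1, ng + 1))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

class TestMaxDiameter:
    def test_single_voxel_uses_largest_spacing(self):
        m = np.zeros((3, 3, 3))
        m[1, 1, 1] = 1
        assert sx.max_diameter(m, (4, 4, 2)) == 4.0

    def test_two_voxels_axis_aligned(self):
        m = np.zeros((8, 3, 3))
        m[1, 1, 1] = 1
        m[6, 1, 1] = 1
        # centers 10 mm apart along x plus one 2 mm voxel
        assert sx.max_diameter(m, (2, 2, 2)) == 12.0

    def test_digitized_sphere_measures_nominal_diameter(self):
        _, mask = sx.generate_lesion_image(
            sx.PhantomSpec(diameter_mm=20, spacing_mm=(2, 2, 2), texture_model="uniform")
        )
        assert abs(sx.max_diameter(mask) - 20.0) <= 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(FeatureError):
            sx.max_diameter(np.zeros((3, 3, 3)), (1, 1, 1))


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

class TestDiscretize:
    def test_equal_width_binning(self):
        d = sx.discretize(np.array([[[0.0, 1, 2, 3]]]), np.ones((1, 1, 4)), 4)
        assert d.levels.tolist() == [[[1, 2, 3, 4]]]

    def test_constant_lesion_collapses_to_one_level(self):
        d = sx.discretize(np.full((2, 2, 2), 5.0), np.ones((2, 2, 2)), 8)
        assert d.n_levels == 1
        assert set(d.levels.ravel()) == {1}

    def test_extremes_map_to_extreme_bins(self):
        d = sx.discretize(np.array([[[0.0, 10.0]]]), np.ones((1, 1, 2)), 2)
        assert d.levels.tolist() == [[[1, 2]]]

    def test_too_few_levels_rejected(self):
        with pytest.raises(FeatureError):
            sx.discretize(np.ones((2, 2, 2)), np.ones((2, 2, 2)), 1)

    def test_all_in_mask_levels_in_range(self, rng):
        vals = rng.random((4, 4, 4)) * 30
        mask = rng.random((4, 4, 4)) < 0.7
        mask.flat[0] = True
        d = sx.discretize(vals, mask, 6)
        inm = d.levels[mask]
        assert inm.min() >= 1 and inm.max() <= 6
        assert (d.levels[~mask] == 0).all()


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

class TestGlcm:
    def test_two_by_two_single_offset(self):
        d = _dlesion([[1, 2], [2, 1]], 2)
        m = sx.compute_glcm(d, offsets=[(0, 1)], symmetric=True)
        assert np.allclose(m.p, [[0, 0.5], [0.5, 0]])

    def test_constant_image_single_diagonal_entry(self):
        d = _dlesion(np.ones((3, 3, 3), dtype=int), 1)
        m = sx.compute_glcm(d)
        assert m.p.shape == (1, 1) and m.p[0, 0] == 1.0

    def test_scattered_voxels_degenerate(self):
        levels = np.zeros((5, 5, 5), dtype=np.int32)
        levels[0, 0, 0] = 1
        levels[4, 4, 4] = 2
        with pytest.raises(DegenerateTextureError):
            sx.compute_glcm(_dlesion(levels, 2))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = random_levels(rng, (4, 4, 4), 3)
        offsets = default_offsets(3)
        try:
            m = sx.compute_glcm(d, offsets=offsets, symmetric=True)
        except DegenerateTextureError:
            pytest.skip("degenerate draw")
        expected = glcm_oracle(d.levels, 3, offsets, symmetric=True)
        assert np.allclose(m.p, expected, atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        d = random_levels(rng, (5, 5, 5), 4)
        m = sx.compute_glcm(d)
        assert abs(m.p.sum() - 1.0) < 1e-12


class TestGlcmFeatures:
    def test_hand_worked_two_level_matrix(self):
        m = GLCMatrix(p=np.array([[0, 0.5], [0.5, 0]]), offsets=((0, 1),), symmetric=True)
        vals, flags = sx.glcm_features(m)
        assert vals["entropy"] == pytest.approx(1.0)
        assert vals["contrast"] == pytest.approx(1.0)
        assert vals["homogeneity"] == pytest.approx(0.5)
        assert vals["correlation"] == pytest.approx(-1.0)
        assert flags == ()

    def test_single_entry_diagonal_limits(self):
        m = GLCMatrix(p=np.array([[1.0]]), offsets=((0, 1),), symmetric=True)
        vals, flags = sx.glcm_features(m)
        assert vals["entropy"] == 0.0
        assert vals["contrast"] == 0.0
        assert vals["homogeneity"] == 1.0
        assert "correlation_degenerate" in flags

    def test_unnormalized_matrix_rejected(self):
        m = GLCMatrix(p=np.array([[1.0, 1.0], [0.0, 0.0]]), offsets=((0, 1),), symmetric=False)
        with pytest.raises(FeatureError):
            sx.glcm_features(m)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = rng.random((3, 3))
        p /= p.sum()
        m = GLCMatrix(p=p, offsets=((0, 1),), symmetric=False)
        vals, _ = sx.glcm_features(m)
        expected = glcm_features_oracle(p)
        for k in vals:
            assert vals[k] == pytest.approx(expected[k], abs=1e-10)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

class TestGlszm:
    def test_two_by_three_hand_flood_fill(self):
        d = _dlesion([[1, 1, 2], [1, 2, 2]], 2)
        z = sx.compute_glszm(d)
        assert z.n_zones == 2
        assert z.Z[0, 2] == 1 and z.Z[1, 2] == 1  # Z(1,3) and Z(2,3)

    def test_single_voxel_single_zone(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        levels[1, 1, 1] = 1
        z = sx.compute_glszm(_dlesion(levels, 1))
        assert z.n_zones == 1 and z.Z[0, 0] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_voxel_conservation_and_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        d = random_levels(rng, (5, 5, 5), 4)
        z = sx.compute_glszm(d)
        sizes = np.arange(1, z.Z.shape[1] + 1)
        assert (z.Z * sizes[None, :]).sum() == (d.levels > 0).sum()
        expected = glszm_oracle(d.levels, 4)
        assert np.array_equal(z.Z, expected)


class TestGlszmFeatures:
    def test_hand_worked_example(self):
        z = sx.compute_glszm(_dlesion([[1, 1, 2], [1, 2, 2]], 2))
        vals = sx.glszm_features(z)
        assert vals["short_zone_emphasis"] == pytest.approx(1 / 9)
        assert vals["size_variation"] == pytest.approx(2.0)
        assert vals["grey_level_uniformity"] == pytest.approx(1.0)

    def test_all_singleton_zones_give_sze_one(self):
        # checkerboard: every zone is a single voxel (26-connectivity needs
        # fully isolated levels, so use 3 alternating levels on a line)
        levels = np.array([[[1, 2, 1, 2, 1]]], dtype=np.int32)
        z = sx.compute_glszm(_dlesion(levels, 2))
        assert z.n_zones == 5
        assert sx.glszm_features(z)["short_zone_emphasis"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        d = random_levels(rng, (4, 4, 4), 3)
        z = sx.compute_glszm(d)
        vals = sx.glszm_features(z)
        expected = glszm_features_oracle(z.Z.astype(float))
        for k in vals:
            assert vals[k] == pytest.approx(expected[k], abs=1e-10)


# ---------------------------------------------------------------------------
# first-order / conventional
# ---------------------------------------------------------------------------

class TestFirstOrder:
    def test_hand_worked_moments(self):
        vals, flags = sx.first_order_features([1, 1, 1, 5])
        assert vals["cov"] == pytest.approx(np.sqrt(3) / 2)
        assert vals["skewness"] == pytest.approx(6 / 3**1.5)
        assert flags == ()

    def test_symmetric_distribution_has_zero_skewness(self):
        vals, _ = sx.first_order_features([1, 2, 3])
        assert vals["skewness"] == pytest.approx(0.0)

    def test_scale_and_affine_invariance(self, rng):
        x = rng.random(50) + 0.5
        cov1 = sx.first_order_features(x)[0]["cov"]
        cov2 = sx.first_order_features(7 * x)[0]["cov"]
        assert cov1 == pytest.approx(cov2)
        sk1 = sx.first_order_features(x)[0]["skewness"]
        sk2 = sx.first_order_features(3 * x + 2)[0]["skewness"]
        assert sk1 == pytest.approx(sk2)

    def test_constant_values_flagged(self):
        vals, flags = sx.first_order_features([4.0, 4.0, 4.0])
        assert vals["cov"] == 0.0 and vals["skewness"] == 0.0
        assert "first_order_degenerate" in flags


class TestConventional:
    def test_volume_and_tre(self):
        mask = np.ones((100, 1, 1))
        vals = sx.conventional_features(np.full(100, 5.0), mask, (2, 2, 2))
        assert vals["volume_ml"] == pytest.approx(0.8)
        assert vals["tre"] == pytest.approx(4.0)

    def test_constant_lesion_max_equals_mean(self):
        mask = np.ones((3, 3, 3))
        vals = sx.conventional_features(np.full(27, 2.5), mask, (1, 1, 1))
        assert vals["suv_max"] == vals["suv_mean"] == 2.5

    def test_tre_identity_on_random_lesions(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            v = rng.random(n) * 20
            vals = sx.conventional_features(v, np.ones(n), rng.random(3) + 0.5)
            assert vals["tre"] == pytest.approx(vals["volume_ml"] * vals["suv_mean"], rel=1e-12)


# ---------------------------------------------------------------------------
# extraction and aggregation
# ---------------------------------------------------------------------------

class TestExtractLesion:
    def test_sub_threshold_lesion_excluded(self):
        suv, mask = make_suv_phantom(diameter_mm=14, spacing=(2, 2, 2), texture="uniform")
        result = sx.extract_lesion(suv, mask)
        assert isinstance(result, LesionExclusion)
        assert result.reason == "below size threshold"
        assert result.diameter_mm < 15

    def test_uniform_phantom_hits_analytic_limits(self):
        suv, mask = make_suv_phantom(diameter_mm=30, texture="uniform")
        fv = sx.extract_lesion(suv, mask)
        assert fv.entropy == 0.0
        assert fv.contrast == 0.0
        assert fv.cov == 0.0
        assert fv.homogeneity == 1.0

    def test_all_features_present_and_finite(self):
        suv, mask = make_suv_phantom(diameter_mm=25, heterogeneity=0.6, seed=3)
        fv = sx.extract_lesion(suv, mask)
        for name in FEATURE_COLUMNS:
            assert np.isfinite(getattr(fv, name)), name

    def test_requires_suv_volume(self):
        vol, mask = sx.generate_lesion_image(sx.PhantomSpec(diameter_mm=25))
        with pytest.raises(FeatureError):
            sx.extract_lesion(vol, mask)

    def test_alignment_mismatch_rejected(self):
        suv, mask = make_suv_phantom(diameter_mm=25)
        bad = sx.LesionMask(np.ones((4, 4, 4), dtype=np.uint8), suv.spacing_mm)
        from sstrtex.errors import AlignmentError

        with pytest.raises(AlignmentError):
            sx.extract_lesion(suv, bad)


class TestAggregate:
    def _fv(self, site="liver", volume=1.0, entropy=2.0):
        fv = FeatureVector(site=site, volume_ml=volume, entropy=entropy)
        for name in FEATURE_COLUMNS:
            if np.isnan(getattr(fv, name)):
                setattr(fv, name, 1.0)
        return fv

    def test_single_lesion_identity(self):
        fv = self._fv()
        agg = sx.aggregate([fv], "per_patient")
        assert agg.entropy == fv.entropy and agg.volume_ml == fv.volume_ml

    def test_per_patient_mean(self):
        agg = sx.aggregate([self._fv(entropy=2.0), self._fv(entropy=4.0)], "per_patient")
        assert agg.entropy == pytest.approx(3.0)

    def test_per_system_keeps_largest_per_site(self):
        lesions = [
            self._fv("liver", volume=1.0, entropy=10.0),
            self._fv("liver", volume=2.0, entropy=20.0),
            self._fv("liver", volume=3.0, entropy=30.0),
            self._fv("lymph_node", volume=0.5, entropy=8.0),
        ]
        agg = sx.aggregate(lesions, "per_system")
        # mean of the largest liver lesion (entropy 30) and the node (8)
        assert agg.entropy == pytest.approx((30.0 + 8.0) / 2)

    def test_no_included_lesions_unanalyzable(self):
        with pytest.raises(FeatureError):
            sx.aggregate([], "per_patient")


# ---------------------------------------------------------------------------
# global invariants
# ---------------------------------------------------------------------------

class TestInvariants:
    def test_bounds_on_random_lesions(self, rng):
        for seed in range(10):
            suv, mask = make_suv_phantom(diameter_mm=22, heterogeneity=float(rng.random()), seed=seed)
            fv = sx.extract_lesion(suv, mask)
            ng = 64
            assert 0 <= fv.entropy <= 2 * np.log2(ng)
            assert 0 < fv.homogeneity <= 1
            assert 0 < fv.short_zone_emphasis <= 1
            assert -1 <= fv.correlation <= 1

    def test_axis_relabeling_invariance(self, rng):
        d = random_levels(rng, (4, 5, 6), 3)
        from sstrtex.features import DiscretizedLesion

        m1 = sx.compute_glcm(d)
        d_t = DiscretizedLesion(
            levels=np.transpose(d.levels, (2, 0, 1)), n_levels=3, bin_edges=d.bin_edges
        )
        m2 = sx.compute_glcm(d_t)
        v1, _ = sx.glcm_features(m1)
        v2, _ = sx.glcm_features(m2)
        for k in v1:
            assert v1[k] == pytest.approx(v2[k], abs=1e-10)
        z1 = sx.glszm_features(sx.compute_glszm(d))
        z2 = sx.glszm_features(sx.compute_glszm(d_t))
        for k in z1:
            assert z1[k] == pytest.approx(z2[k], abs=1e-10)
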