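"""Texture matrices against exhaustive enumeration oracles, plus invariants."""

import numpy as np
import pytest
from scipy import ndimage

import mpradiomics as mp
from mpradiomics.features import (
    first_order_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
)
from mpradiomics.features._directions import DIRECTIONS_3D

from conftest import region_from_levels


# ------------------------------------------------------------- oracles


def glcm_oracle(levels, directions):
    """Exhaustive voxel-pair enumeration (both orientations), normalized."""
    levels = np.asarray(levels)
    L = levels.max()
    counts = np.zeros((L, L), float)
    for idx in np.argwhere(levels > 0):
        for d in directions:
            for sgn in (1, -1):
                q = tuple(idx + sgn * np.asarray(d))
                if all(0 <= qi < n for qi, n in zip(q, levels.shape)) and levels[q] > 0:
                    counts[levels[tuple(idx)] - 1, levels[q] - 1] += 1
    return counts / counts.sum()


def glrlm_oracle(levels, directions):
    """Brute-force run scanner: walk every maximal run along each direction."""
    levels = np.asarray(levels)
    L = levels.max()
    runs = {}
    for d in directions:
        d = np.asarray(d)
        for idx in np.argwhere(levels > 0):
            prev = idx - d
            if (all(0 <= p < n for p, n in zip(prev, levels.shape))
                    and levels[tuple(prev)] == levels[tuple(idx)]):
                continue  # not a run start
            length = 1
            cur = idx + d
            while (all(0 <= c < n for c, n in zip(cur, levels.shape))
                   and levels[tuple(cur)] == levels[tuple(idx)]
                   and levels[tuple(cur)] > 0):
                length += 1
                cur = cur + d
            key = (levels[tuple(idx)], length)
            runs[key] = runs.get(key, 0) + 1
    max_len = max(k[1] for k in runs)
    m = np.zeros((L, max_len), float)
    for (lv, ln), c in runs.items():
        m[lv - 1, ln - 1] = c
    return m


def glszm_oracle(levels):
    """Per-level 26-connected flood fill."""
    levels = np.asarray(levels)
    L = levels.max()
    structure = np.ones((3, 3, 3))
    zones = []
    for lv in range(1, L + 1):
        lab, n = ndimage.label(levels == lv, structure=structure)
        for k in range(1, n + 1):
            zones.append((lv, int((lab == k).sum())))
    max_size = max(s for _, s in zones)
    m = np.zeros((L, max_size), float)
    for lv, s in zones:
        m[lv - 1, s - 1] += 1
    return m


# ----------------------------------------------------------- first order


class TestFirstOrder:
    def test_tiny_example(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0]))
        assert f["mean"] == 2 and f["median"] == 2 and f["range"] == 2
        assert f["minimum"] == 1 and f["maximum"] == 3
        assert f["energy"] == pytest.approx(14.0)

    def test_constant_sample(self):
        f = first_order_features(np.full(50, 7.0))
        assert f["variance"] == 0 and f["entropy"] == 0 and f["uniformity"] == 1

    def test_normal_moments(self):
        rng = np.random.default_rng(0)
        f = first_order_features(rng.standard_normal(1000))
        assert f["skewness"] == pytest.approx(0.0, abs=0.3)
        assert f["kurtosis"] == pytest.approx(3.0, abs=0.3)  # non-excess

    def test_exactly_twelve_titles(self):
        f = first_order_features(np.arange(10.0))
        assert len(f) == 12


# ------------------------------------------------------------- subregions


class TestSubregions:
    def test_set_arithmetic(self):
        lm = np.zeros((40, 1, 1), dtype=int)
        lm[0:10, 0, 0] = 1
        lm[10:20, 0, 0] = 2
        lm[20:30, 0, 0] = 3
        lm[30:40, 0, 0] = 4
        masks = mp.derive_subregions(lm)
        assert masks["solid_core"].sum() == 30
        assert masks["whole_tumor"].sum() == 40

    def test_no_edema_solid_core_equals_whole(self):
        lm = np.zeros((5, 5, 5), dtype=int)
        lm[1:3] = 1
        masks = mp.derive_subregions(lm)
        assert np.array_equal(masks["solid_core"], masks["whole_tumor"])

    def test_empty_whole_tumor_errors(self):
        with pytest.raises(ValueError, match="whole tumor"):
            mp.derive_subregions(np.zeros((4, 4, 4), dtype=int))


# ------------------------------------------------------------------ GLCM


class TestGLCM:
    def test_single_pair(self):
        region = region_from_levels(np.array([[[1, 2]]]))
        p = glcm_matrix(region)
        assert p[0, 1] == 0.5 and p[1, 0] == 0.5
        assert p[0, 0] == 0 and p[1, 1] == 0

    def test_constant_region(self):
        region = region_from_levels(np.full((3, 3, 1), 2), n_levels=4)
        p = glcm_matrix(region)
        assert p[1, 1] == 1.0 and p.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(1, 5, size=(4, 4, 2))
        levels[rng.random(levels.shape) < 0.2] = 0  # holes in the mask
        if not (levels > 0).any():
            levels[0, 0, 0] = 1
        region = region_from_levels(levels, n_levels=4)
        p = glcm_matrix(region)
        np.testing.assert_allclose(p[: levels.max(), : levels.max()],
                                   glcm_oracle(levels, DIRECTIONS_3D), atol=1e-12)

    def test_matrix_properties(self):
        rng = np.random.default_rng(1)
        region = region_from_levels(rng.integers(1, 7, size=(5, 5, 3)))
        p = glcm_matrix(region)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, p.T)

    def test_idmn_on_diagonal_matrix(self):
        L = 4
        p = np.eye(L) / L
        f = glcm_features(p)
        assert f["IDMN"] == pytest.approx(1.0)
        assert f["IDN"] == pytest.approx(1.0)

    def test_imc2_zero_for_independent_marginals(self):
        marg = np.array([0.1, 0.2, 0.3, 0.4])
        f = glcm_features(np.outer(marg, marg))
        assert f["IMC2"] == pytest.approx(0.0, abs=1e-8)

    def test_two_by_two_direct_summation(self):
        """Every statistic of [[0.4, 0.1], [0.1, 0.4]] against hand formulas."""
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        f = glcm_features(p)
        # marginals (0.5, 0.5); mu = 1.5, sd^2 = 0.25
        assert f["autocorrelation"] == pytest.approx(0.4 * 1 + 0.1 * 2 + 0.1 * 2 + 0.4 * 4)
        assert f["contrast"] == pytest.approx(0.2)
        assert f["dissimilarity"] == pytest.approx(0.2)
        assert f["energy"] == pytest.approx(2 * 0.4 ** 2 + 2 * 0.1 ** 2)
        assert f["max_probability"] == pytest.approx(0.4)
        assert f["correlation"] == pytest.approx((2.4 - 2.25) / 0.25)
        assert f["homogeneity1"] == pytest.approx(0.8 + 0.2 / 2)
        assert f["homogeneity2"] == pytest.approx(0.8 + 0.2 / 2)
        assert f["IDMN"] == pytest.approx(0.8 + 0.2 / (1 + 0.25))
        assert f["IDN"] == pytest.approx(0.8 + 0.2 / 1.5)
        assert f["inverse_variance"] == pytest.approx(0.2)
        assert f["variance"] == pytest.approx(0.25)
        assert f["cluster_tendency"] == pytest.approx(
            sum(p[i, j] * (i + j + 2 - 3.0) ** 2 for i in range(2) for j in range(2)))
        assert f["entropy"] == pytest.approx(
            -2 * (0.4 * np.log2(0.4) + 0.1 * np.log2(0.1)))
        # sum distribution: p(2)=0.4, p(3)=0.2, p(4)=0.4
        assert f["sum_average"] == pytest.approx(3.0)
        assert f["sum_variance"] == pytest.approx(0.4 * 1 + 0.4 * 1)
        assert f["sum_entropy"] == pytest.approx(
            -(0.8 * np.log2(0.4) + 0.2 * np.log2(0.2)))
        assert f["difference_entropy"] == pytest.approx(
            -(0.8 * np.log2(0.8) + 0.2 * np.log2(0.2)))
        hxy = f["entropy"]
        hxy2 = -np.sum(np.outer([0.5, 0.5], [0.5, 0.5])
                       * np.log2(np.outer([0.5, 0.5], [0.5, 0.5])))
        assert f["IMC2"] == pytest.approx(np.sqrt(1 - np.exp(-2 * (hxy2 - hxy))))
        assert len(f) == 22


# ----------------------------------------------------------------- GLRLM


class TestGLRLM:
    def test_single_line_run(self):
        levels = np.array([[[1, 1, 1]]])
        region = region_from_levels(levels)
        m = glrlm_matrix(region, directions=[(0, 0, 1)])
        assert m[0, 2] == 1 and m.sum() == 1
        f = glrlm_features(m, n_voxels=3)
        assert f["RP"] == pytest.approx(1 / 3)

    def test_constant_region_hgre(self):
        L = 5
        region = region_from_levels(np.full((3, 3, 3), L), n_levels=L)
        m = glrlm_matrix(region)
        f = glrlm_features(m, n_voxels=27)
        assert f["HGRE"] == pytest.approx(L ** 2)
        assert f["LGRE"] == pytest.approx(1.0 / L ** 2)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_scanner(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(1, 4, size=(4, 4, 1))
        region = region_from_levels(levels, n_levels=3)
        m = glrlm_matrix(region)
        oracle = glrlm_oracle(levels, DIRECTIONS_3D)
        np.testing.assert_allclose(m[:, : oracle.shape[1]], oracle)
        assert m[:, oracle.shape[1]:].sum() == 0

    def test_thirteen_statistics(self):
        region = region_from_levels(np.arange(1, 9).reshape(2, 2, 2))
        f = glrlm_features(glrlm_matrix(region), n_voxels=8)
        assert len(f) == 13


# ----------------------------------------------------------------- GLSZM


class TestGLSZM:
    def test_two_singleton_zones(self):
        levels = np.zeros((3, 3, 1), dtype=int)
        levels[0, 0, 0] = 1
        levels[2, 2, 0] = 2
        # diagonal voxels are 26-connected only if adjacent; (0,0) and (2,2) are not
        region = region_from_levels(levels)
        m = glszm_matrix(region)
        f = glszm_features(m, n_voxels=2)
        assert m.sum() == 2
        assert f["GLN"] == pytest.approx(1.0)

    def test_single_zone(self):
        region = region_from_levels(np.full((2, 2, 2), 3), n_levels=3)
        m = glszm_matrix(region)
        f = glszm_features(m, n_voxels=8)
        assert m.sum() == 1
        assert f["GLN"] == pytest.approx(1.0)
        assert f["ZP"] == pytest.approx(1 / 8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 4, size=(5, 4, 3))
        if not (levels > 0).any():
            levels[0, 0, 0] = 1
        region = region_from_levels(levels, n_levels=3)
        m = glszm_matrix(region)
        oracle = glszm_oracle(levels)
        np.testing.assert_allclose(m[: oracle.shape[0], : oracle.shape[1]], oracle)

    def test_twelve_statistics(self):
        region = region_from_levels(np.arange(1, 9).reshape(2, 2, 2))
        f = glszm_features(glszm_matrix(region), n_voxels=8)
        assert len(f) == 12


# ----------------------------------------------------------------- NGTDM


class TestNGTDM:
    def test_constant_region(self):
        region = region_from_levels(np.full((3, 3, 3), 2), n_levels=2)
        n, s, N = ngtdm_table(region)
        f = ngtdm_features(n, s, N)
        assert f["contrast"] == 0.0
        assert f["coarseness"] == 1e6  # capped at the documented maximum

    def test_hand_computed_plane(self):
        """3x3x1 alternating pattern: verify s(i) by explicit enumeration."""
        levels = np.array([[[1], [2], [1]],
                           [[2], [1], [2]],
                           [[1], [2], [1]]])
        region = region_from_levels(levels)
        n, s, N = ngtdm_table(region)
        assert N == 9
        # per-voxel neighbourhood means computed by hand:
        # corners (level 1): neighbours {2,2,1} -> mean 5/3; center: mean 12/8
        # edges (level 2): neighbours {1,1,2,1,2} -> mean 7/5
        expect_s1 = abs(1 - 5 / 3) * 4 + abs(1 - 1.5)
        expect_s2 = abs(2 - 7 / 5) * 4
        assert n.tolist() == [5, 4]
        assert s[0] == pytest.approx(expect_s1)
        assert s[1] == pytest.approx(expect_s2)
        f = ngtdm_features(n, s, N)
        assert len(f) == 5 and all(np.isfinite(v) for v in f.values())

    def test_finite_on_random_region(self):
        rng = np.random.default_rng(2)
        region = region_from_levels(rng.integers(1, 6, size=(6, 6, 6)))
        f = ngtdm_features(*ngtdm_table(region))
        assert all(np.isfinite(v) for v in f.values())


# ------------------------------------------------------------- invariants


class TestInvariances:
    def _region(self, seed=0, shape=(6, 6, 4), L=5):
        rng = np.random.default_rng(seed)
        return region_from_levels(rng.integers(1, L + 1, size=shape), n_levels=L)

    def test_rotation_consistency(self):
        """Axis-aligned 90-degree rotation leaves pooled GLCM/GLRLM features
        unchanged (the 13-direction set maps onto itself up to sign)."""
        region = self._region()
        rot = region_from_levels(np.rot90(region.levels, k=1, axes=(0, 1)),
                                 n_levels=region.n_levels)
        f0, f1 = glcm_features(glcm_matrix(region)), glcm_features(glcm_matrix(rot))
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], rel=1e-10), k
        n_vox = int(region.mask.sum())
        g0 = glrlm_features(glrlm_matrix(region), n_vox)
        g1 = glrlm_features(glrlm_matrix(rot), n_vox)
        for k in g0:
            assert g0[k] == pytest.approx(g1[k], rel=1e-10), k

    def test_intensity_shift_invariance_of_high_order(self, small_phantom):
        """Adding a constant to a modality leaves every high-order feature
        unchanged: quantization is range-based."""
        shifted = mp.MultimodalStudy(
            patient_id=small_phantom.patient_id,
            volumes={m: v + 250.0 for m, v in small_phantom.volumes.items()},
            label_map=small_phantom.label_map.copy(),
            spacing=small_phantom.spacing,
        )
        grid = [mp.ParameterSetting(1.0, q, 32)
                for q in ("uniform", "equal_probability", "lloyd_max")]
        r0 = mp.extract_study(small_phantom, grid)
        r1 = mp.extract_study(shifted, grid)
        high = [c for c in r0.index if "firstorder" not in c]
        np.testing.assert_allclose(r0[high].to_numpy(), r1[high].to_numpy(),
                                   rtol=1e-8, atol=1e-10)


# ------------------------------------------------------------- extraction


class TestExtraction:
    def test_column_count_arithmetic(self, full_grid):
        assert mp.expected_feature_count(full_grid) == 45_792

    def test_no_edema_yields_missing_edema_columns(self, small_spec):
        study = mp.generate_phantom(small_spec, 2)
        lm = study.label_map.copy()
        lm[lm == 2] = 0  # remove edema
        no_edema = mp.MultimodalStudy(study.patient_id, study.volumes, lm,
                                      study.spacing)
        grid = [mp.ParameterSetting(1.0, "uniform", 32)]
        row = mp.extract_study(no_edema, grid)
        edema_cols = [c for c in row.index if "_edema_" in c]
        other_cols = [c for c in row.index if "_edema_" not in c]
        assert row[edema_cols].isna().all()
        assert not row[other_cols].isna().any()

    def test_feature_key_roundtrip(self):
        key = mp.FeatureKey.parse("T1C_non_enhancing_GLCM_cluster_shade@VS2|Eq|GL64")
        assert key.modality == "T1C"
        assert key.region == "non_enhancing"
        assert key.family == "GLCM"
        assert key.title == "cluster_shade"
        assert key.setting == mp.ParameterSetting(2.0, "equal_probability", 64)
        assert key.column == "T1C_non_enhancing_GLCM_cluster_shade@VS2|Eq|GL64"
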