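"""Shape, discretization, first-order and GLRLM feature definitions."""

import numpy as np
import pytest

from _oracles import brute_max_diameters, enumerate_runs, glrlm_from_runs
from gliosurv import features
from gliosurv.features import DiscretizationSpec


class TestShape:
    def test_two_voxel_345_triangle(self):
        m = np.zeros((5, 6, 2), bool)
        m[0, 0, 0] = m[3, 4, 0] = True
        sf = features.shape_features(m, (1, 1, 1))
        assert sf["max_3d_diameter_mm"] == pytest.approx(5.0)
        assert sf["max_2d_diameter_axial_mm"] == pytest.approx(5.0)

    def test_volume_in_ml(self):
        m = np.zeros((5, 5, 5), bool)
        m.flat[:10] = True
        sf = features.shape_features(m, (2, 2, 2))
        assert sf["volume_ml"] == pytest.approx(0.08)

    def test_cube_surface_and_sphericity(self):
        m = np.zeros((6, 6, 6), bool)
        m[1:4, 1:4, 1:4] = True  # 3x3x3 cube, 1 mm spacing
        sf = features.shape_features(m, (1, 1, 1))
        assert sf["surface_area_mm2"] == pytest.approx(54.0)
        v, a = 27.0, 54.0
        assert sf["sphericity"] == pytest.approx(
            np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / a
        )

    def test_diameters_match_brute_force(self, rng):
        spacing = (1.0, 1.5, 2.0)
        for _ in range(8):
            m = rng.random((12, 12, 12)) < 0.05
            if m.sum() < 2:
                continue
            sf = features.shape_features(m, spacing)
            want = brute_max_diameters(m, spacing)
            assert sf["max_3d_diameter_mm"] == pytest.approx(want["max_3d"], abs=1e-12)
            for plane in ("axial", "coronal", "sagittal"):
                assert sf[f"max_2d_diameter_{plane}_mm"] == pytest.approx(
                    want[plane], abs=1e-12
                )

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            features.shape_features(np.zeros((3, 3, 3), bool), (1, 1, 1))


class TestDiscretize:
    def test_full_range_bijection(self):
        img = np.arange(32, dtype=float).reshape(2, 4, 4)
        mask = np.ones_like(img, bool)
        lab = features.discretize(img, mask, DiscretizationSpec(32))
        assert sorted(lab[mask]) == list(range(1, 33))
        assert (np.argsort(lab[mask].ravel()) == np.argsort(img[mask].ravel())).all()

    def test_constant_roi_all_label_one(self):
        img = np.full((2, 2, 2), 7.0)
        lab = features.discretize(img, np.ones_like(img, bool))
        assert (lab == 1).all()

    def test_top_edge_inclusive(self):
        img = np.array([0.0, 5.0, 10.0]).reshape(1, 1, 3)
        lab = features.discretize(img, np.ones_like(img, bool), DiscretizationSpec(4))
        assert lab[0, 0, 2] == 4  # the maximum lands in the top bin


class TestFirstOrder:
    def test_basic_statistics(self):
        img = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
        f = features.first_order_features(img, np.ones_like(img, bool))
        assert f["mean"] == 2.5
        assert f["range"] == 3.0
        assert f["energy"] == 30.0

    def test_two_level_entropy_one_bit(self):
        img = np.array([0.0, 0.0, 1.0, 1.0]).reshape(1, 1, 4)
        f = features.first_order_features(
            img, np.ones_like(img, bool), DiscretizationSpec(2)
        )
        assert f["entropy"] == pytest.approx(1.0)
        assert f["uniformity"] == pytest.approx(0.5)

    def test_constant_roi_degenerate_moments(self):
        img = np.full((1, 1, 5), 3.0)
        f = features.first_order_features(img, np.ones_like(img, bool))
        assert f["variance"] == 0.0
        assert f["entropy"] == 0.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0


class TestGLRLM:
    def test_hand_enumerated_line(self):
        lab = np.array([1, 1, 2]).reshape(1, 1, 3)
        per_dir = features.glrlm_features(lab, average=False)
        along = per_dir[features.DIRECTIONS.index((0, 0, 1))]
        assert along["rp"] == pytest.approx(2 / 3)
        assert along["sre"] == pytest.approx(0.625)

    def test_constant_line_long_run(self):
        lab = np.ones((1, 1, 3), int)
        along = features.glrlm_features(lab, average=False)[
            features.DIRECTIONS.index((0, 0, 1))
        ]
        assert along["lre"] == pytest.approx(9.0)
        assert along["sre"] == pytest.approx(1 / 9)
        assert along["rp"] == pytest.approx(1 / 3)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            lab = rng.integers(1, 5, size=(6, 6, 6))
            lab[rng.random(lab.shape) < 0.3] = 0  # holes end runs
            if (lab > 0).sum() == 0:
                continue
            n_vox = int((lab > 0).sum())
            got = features.glrlm_features(lab, average=False)
            for d, g in zip(features.DIRECTIONS, got):
                runs = enumerate_runs(lab, d)
                want = glrlm_from_runs(runs, int(lab.max()), n_vox)
                for k in features.GLRLM_FEATURES:
                    assert g[k] == pytest.approx(want[k], abs=1e-10), (d, k)

    def test_run_length_conservation(self, rng):
        lab = rng.integers(0, 4, size=(7, 7, 7))
        n_vox = (lab > 0).sum()
        for d in features.DIRECTIONS:
            P = features.run_length_matrix(lab, d)
            lengths = np.arange(P.shape[1])
            assert (P.sum(axis=0) * lengths).sum() == n_vox


class TestInvariances:
    @pytest.fixture()
    def textured_roi(self, rng):
        img = rng.normal(size=(10, 10, 10))
        mask = np.zeros_like(img, bool)
        mask[2:8, 2:8, 2:8] = True
        mask &= rng.random(img.shape) < 0.9
        return img, mask

    def test_axial_rotation_invariance(self, textured_roi):
        img, mask = textured_roi
        f0 = features.glrlm_features(features.discretize(img, mask))
        s0 = features.shape_features(mask, (1, 1, 1))
        img_r = np.rot90(img, axes=(0, 1))
        mask_r = np.rot90(mask, axes=(0, 1))
        f1 = features.glrlm_features(features.discretize(img_r, mask_r))
        s1 = features.shape_features(mask_r, (1, 1, 1))
        for k in features.GLRLM_FEATURES:
            assert f1[k] == pytest.approx(f0[k], abs=1e-9)
        for k in features.SHAPE_FEATURES:
            assert s1[k] == pytest.approx(s0[k], abs=1e-9)

    def test_intensity_shift_invariance(self, textured_roi):
        img, mask = textured_roi
        g0 = features.glrlm_features(features.discretize(img, mask))
        f0 = features.first_order_features(img, mask)
        g1 = features.glrlm_features(features.discretize(img + 5.0, mask))
        f1 = features.first_order_features(img + 5.0, mask)
        for k in features.GLRLM_FEATURES:
            assert g1[k] == pytest.approx(g0[k], abs=1e-9)
        assert f1["mean"] == pytest.approx(f0["mean"] + 5.0)
        assert f1["variance"] == pytest.approx(f0["variance"], rel=1e-12)
        assert f1["entropy"] == pytest.approx(f0["entropy"], abs=1e-12)
        assert f1["uniformity"] == pytest.approx(f0["uniformity"], abs=1e-12)


class TestFeatureTable:
    def test_inventory_and_missing_zone_contract(self, rng):
        img = rng.normal(size=(8, 8, 8))
        full = np.zeros((8, 8, 8), bool)
        full[2:6, 2:6, 2:6] = True
        empty = np.zeros_like(full)
        images = {"p0": {"t1c": img, "flair": img + 1}}
        zones_ = {
            "p0": {
                "tumor": full,
                "band_pm5": full,
                "ptz_0_10": full,
                "ptz_10_20": empty,
            }
        }
        tab = features.extract_feature_table(images, zones_, (1, 1, 1))
        assert tab.shape == (1, 292)
        ptz_cols = [c for c in tab.columns if c.startswith("ptz_10_20_")]
        other = [c for c in tab.columns if not c.startswith("ptz_10_20_")]
        assert tab[ptz_cols].isna().all().all()
        assert tab[other].notna().all().all()

    def test_geometry_mismatch_errors(self, rng):
        images = {"p0": {"t1c": rng.normal(size=(4, 4, 4))}}
        zones_ = {"p0": {"tumor": np.ones((5, 5, 5), bool)}}
        with pytest.raises(ValueError, match="geometry"):
            features.extract_feature_table(images, zones_, (1, 1, 1))
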