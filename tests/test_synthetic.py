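"""Synthetic cohort generator: geometry, texture, survival, cohort assembly."""

import numpy as np
import pandas as pd
import pytest

from gliosurv import features, synthetic
from gliosurv.synthetic import CensoringConfig, SyntheticConfig


@pytest.fixture(scope="module")
def cfg():
    return SyntheticConfig(n_patients=4, seed=0)


class TestTumorMask:
    @staticmethod
    def _fine_grid():
        return SyntheticConfig(
            grid_shape=(72, 72, 72),
            voxel_spacing_mm=(1, 1, 1),
            radius_mm_range=(5.0, 10.0),
            lobulation=0.0,
            center_jitter_mm=0.0,
        )

    def test_sphere_volume_analytic(self):
        mask = synthetic.generate_tumor_mask(self._fine_grid(), (10, 10, 10), 0.0, seed=1)
        vol = mask.sum()  # 1 mm voxels
        assert vol == pytest.approx(4 / 3 * np.pi * 10**3, rel=0.05)

    def test_sphere_diameter(self):
        mask = synthetic.generate_tumor_mask(self._fine_grid(), (10, 10, 10), 0.0, seed=1)
        sf = features.shape_features(mask, (1, 1, 1))
        assert abs(sf["max_3d_diameter_mm"] - 20.0) <= np.sqrt(3.0)

    def test_deterministic_per_seed(self, cfg):
        a = synthetic.generate_tumor_mask(cfg, (16, 18, 15), 0.2, seed=7)
        b = synthetic.generate_tumor_mask(cfg, (16, 18, 15), 0.2, seed=7)
        assert (a == b).all()
        c = synthetic.generate_tumor_mask(cfg, (16, 18, 15), 0.2, seed=8)
        assert (a != c).any()

    def test_single_connected_component(self, cfg):
        from scipy import ndimage

        mask = synthetic.generate_tumor_mask(cfg, (20, 16, 18), 0.3, seed=3)
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_margin_violation_errors(self, cfg):
        with pytest.raises(ValueError, match="margin"):
            synthetic.generate_tumor_mask(cfg, (50, 50, 50), 0.0, seed=0)


class TestMRIPair:
    def test_long_runs_monotone_in_blob_size(self):
        """GLRLM long-run emphasis grows with texture correlation length."""
        c = SyntheticConfig(noise_sd=0.0)
        mask = synthetic.generate_tumor_mask(c, (20, 20, 20), 0.0, seed=1)
        brain = synthetic.brain_mask(c)
        means = []
        for blob in (4.0, 6.0, 9.0, 13.0, 18.0):
            vals = []
            for s in range(10):
                imgs = synthetic.synthesize_mri_pair(mask, brain, blob, c, 100 + s)
                lab = features.discretize(imgs["t1c"], mask)
                vals.append(features.glrlm_features(lab)["lre"])
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_single_blob_zero_variance(self):
        c = SyntheticConfig(noise_sd=0.0)
        mask = synthetic.generate_tumor_mask(c, (15, 15, 15), 0.0, seed=1)
        imgs = synthetic.synthesize_mri_pair(mask, synthetic.brain_mask(c), None, c, 5)
        for vol in imgs.values():
            assert np.var(vol[mask]) == 0.0

    def test_deterministic_and_sequence_contrast(self):
        c = SyntheticConfig()
        mask = synthetic.generate_tumor_mask(c, (15, 15, 15), 0.0, seed=1)
        brain = synthetic.brain_mask(c)
        a = synthetic.synthesize_mri_pair(mask, brain, 8.0, c, 9)
        b = synthetic.synthesize_mri_pair(mask, brain, 8.0, c, 9)
        assert all((a[s] == b[s]).all() for s in a)
        bg = brain & ~mask
        assert abs(a["t1c"][bg].mean() - 100.0) < 1.0
        assert abs(a["flair"][bg].mean() - 80.0) < 1.0

    def test_nonpositive_blob_errors(self):
        c = SyntheticConfig()
        mask = synthetic.generate_tumor_mask(c, (15, 15, 15), 0.0, seed=1)
        with pytest.raises(ValueError):
            synthetic.synthesize_mri_pair(mask, synthetic.brain_mask(c), -1.0, c, 0)


class TestOutcomes:
    def test_null_betas_give_chance_concordance(self):
        from gliosurv.evaluation import harrell_c

        n = 2000
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({"x": rng.normal(size=n)})
        c = SyntheticConfig(beta={"x": 0.0}, censoring=None)
        out = synthetic.simulate_outcomes(feats, c, seed=1)
        est = harrell_c(out["time_years"], out["event"], feats["x"]).estimate
        assert est == pytest.approx(0.5, abs=0.03)

    def test_no_censoring_all_events(self):
        feats = pd.DataFrame({"x": np.zeros(50)})
        c = SyntheticConfig(beta={"x": 0.3}, censoring=None)
        out = synthetic.simulate_outcomes(feats, c, seed=2)
        assert (out["event"] == 1).all()

    def test_exponential_mean_matches_scale(self):
        feats = pd.DataFrame({"x": np.zeros(5000)})
        c = SyntheticConfig(
            beta={"x": 1.0}, weibull_shape=1.0, weibull_scale=10.0, censoring=None
        )
        out = synthetic.simulate_outcomes(feats, c, seed=3)
        assert out["time_years"].mean() == pytest.approx(10.0, rel=0.05)

    def test_event_fraction_calibration(self):
        rng = np.random.default_rng(4)
        feats = pd.DataFrame({"x": rng.normal(size=1000)})
        c = SyntheticConfig(beta={"x": 0.8}, event_fraction_target=0.25)
        out = synthetic.simulate_outcomes(feats, c, seed=5)
        assert out["event"].mean() == pytest.approx(0.25, abs=0.05)

    def test_invalid_weibull_errors(self):
        with pytest.raises(ValueError):
            SyntheticConfig(weibull_shape=-1.0)


class TestCohort:
    def test_complete_inventory(self):
        co = synthetic.generate_cohort(SyntheticConfig(n_patients=10, seed=2))
        assert len(co.images) == 10
        assert len(co.masks) == 10
        assert len(co.clinical) == 10
        assert len(co.outcomes) == 10
        assert all(set(v) == {"t1c", "flair"} for v in co.images.values())

    def test_clinical_invariants(self):
        co = synthetic.generate_cohort(SyntheticConfig(n_patients=30, seed=3))
        clin = co.clinical
        complete = clin["extent_of_resection"] == "complete"
        assert (clin.loc[complete, "postop_volume_ml"] == 0.0).all()
        assert (clin["postop_volume_ml"] <= clin["preop_volume_ml"] + 1e-9).all()
        assert set(clin["subtype"]) <= {"astrocytoma", "oligodendroglioma"}

    def test_masks_inside_brain_with_margin(self):
        from gliosurv import zones

        co = synthetic.generate_cohort(SyntheticConfig(n_patients=3, seed=4))
        for pid in co.patient_ids:
            assert not (co.masks[pid] & ~co.brain).any()
            z = zones.extract_all_zones(
                co.masks[pid], co.brain, co.config.voxel_spacing_mm
            )
            band = z["ptz_10_20"]
            # outermost zone never touches the grid border
            assert not band[0].any() and not band[-1].any()
            assert not band[:, 0].any() and not band[:, -1].any()
            assert not band[:, :, 0].any() and not band[:, :, -1].any()

    def test_roundtrip_through_disk(self, tmp_path):
        co = synthetic.generate_cohort(SyntheticConfig(n_patients=2, seed=5))
        co.write(tmp_path)
        back = synthetic.load_cohort(tmp_path)
        pid = co.patient_ids[0]
        assert (back.masks[pid] == co.masks[pid]).all()
        assert np.allclose(back.images[pid]["t1c"], co.images[pid]["t1c"])
        pd.testing.assert_frame_equal(back.clinical, co.clinical)

    def test_byte_identical_csvs_across_runs(self, tmp_path):
        cfg = SyntheticConfig(n_patients=3, seed=6)
        synthetic.generate_cohort(cfg, out_dir=tmp_path / "a")
        synthetic.generate_cohort(cfg, out_dir=tmp_path / "b")
        for name in ("clinical.csv", "outcomes.csv", "drivers.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_missing_cohort_files_reported(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="missing"):
            synthetic.load_cohort(tmp_path)
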