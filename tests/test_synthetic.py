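"""Synthetic cohort and blob-slide generators: reproducibility, planted
structure, censoring calibration."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from milsurv.synthetic import (
    INTERVAL_WIDTH_MONTHS,
    SyntheticConfig,
    SyntheticSlideSpec,
    generate_cohort,
    generate_slide_image,
)


class TestConfigValidation:
    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_patients=1)

    def test_bad_bag_range(self):
        with pytest.raises(ValueError):
            SyntheticConfig(bag_size_range=(10, 5))

    def test_bad_baseline_hazards(self):
        with pytest.raises(ValueError):
            SyntheticConfig(baseline_hazards=(0.1, 0.2, 0.3, 1.0))

    def test_bad_informative_fraction(self):
        with pytest.raises(ValueError):
            SyntheticConfig(informative_fraction=0.0)


class TestCohort:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(SyntheticConfig(n_patients=20, seed=4))
        b = generate_cohort(SyntheticConfig(n_patients=20, seed=4))
        for ba, bb in zip(a.bags, b.bags):
            np.testing.assert_array_equal(ba.features, bb.features)
        for ra, rb in zip(a.clinical, b.clinical):
            assert ra.os_months == rb.os_months and ra.censored == rb.censored

    def test_no_censoring_when_rate_zero(self):
        co = generate_cohort(SyntheticConfig(n_patients=40, censoring_rate=0.0, seed=2))
        assert all(r.censored == 0 for r in co.clinical)

    def test_censored_fraction_near_target(self):
        # reference split: 90 cases, one third censored
        co = generate_cohort(SyntheticConfig(n_patients=90, censoring_rate=1 / 3, seed=7))
        frac = np.mean([r.censored for r in co.clinical])
        assert abs(frac - 1 / 3) <= 0.10

    def test_times_fall_in_labeled_interval(self):
        co = generate_cohort(SyntheticConfig(n_patients=50, seed=9))
        for r, t in zip(co.clinical, co.truth):
            y_obs = int(r.os_months // INTERVAL_WIDTH_MONTHS)
            assert 0 <= y_obs <= 3
            if r.censored == 0:
                assert y_obs == t.true_event_interval

    def test_planted_shift_recovered_on_u(self):
        """Informative-minus-background mean, projected on u, equals the
        planted shift within 3 standard errors."""
        co = generate_cohort(SyntheticConfig(
            n_patients=60, bag_size_range=(40, 60), seed=5,
        ))
        inf_proj, bg_proj = [], []
        for bag, t in zip(co.bags, co.truth):
            proj = bag.features @ co.signal_direction
            mask = np.zeros(bag.n_patches, bool)
            mask[t.informative_patch_indices] = True
            inf_proj.extend(proj[mask])
            bg_proj.extend(proj[~mask])
        assert len(inf_proj) + len(bg_proj) >= 1000
        diff = np.mean(inf_proj) - np.mean(bg_proj)
        se = np.sqrt(np.var(inf_proj) / len(inf_proj) + np.var(bg_proj) / len(bg_proj))
        assert abs(diff - co.config.signal_strength) <= 3 * se

    def test_zero_signal_events_follow_baseline(self):
        cfg = SyntheticConfig(
            n_patients=2000, signal_strength=0.0, censoring_rate=0.0,
            bag_size_range=(2, 4), feature_dim=4, seed=3,
        )
        co = generate_cohort(cfg)
        y = np.array([int(r.os_months // INTERVAL_WIDTH_MONTHS) for r in co.clinical])
        base = np.asarray(cfg.baseline_hazards)
        surv = 1.0
        for r in range(3):
            p = surv * base[r]
            se = np.sqrt(p * (1 - p) / y.size)
            assert np.mean(y == r) == pytest.approx(p, abs=4 * se)
            surv *= 1 - base[r]

    def test_latent_risk_anticipates_event_time(self):
        """Higher planted risk => earlier observed events (rank association)."""
        co = generate_cohort(SyntheticConfig(n_patients=200, seed=1))
        cens = np.array([r.censored for r in co.clinical])
        y = np.array([int(r.os_months // INTERVAL_WIDTH_MONTHS) for r in co.clinical])
        z = np.array([t.latent_risk for t in co.truth])
        rho = spearmanr(z[cens == 0], y[cens == 0]).statistic
        assert rho < -0.3

    def test_roundtrip_to_dir(self, tmp_path):
        from milsurv.data import read_bag, read_clinical

        co = generate_cohort(SyntheticConfig(n_patients=5, seed=8))
        co.to_dir(tmp_path)
        clin = read_clinical(tmp_path / "clinical.tsv")
        assert [r.patient_id for r in clin] == [b.patient_id for b in co.bags]
        bag = read_bag(tmp_path / "bags" / f"{co.bags[0].patient_id}.h5")
        np.testing.assert_allclose(bag.features, co.bags[0].features, rtol=1e-6)
        assert (tmp_path / "truth.tsv").exists()


class TestSlideImages:
    def test_no_blobs_is_pure_white(self):
        img, mask = generate_slide_image(SyntheticSlideSpec(n_blobs=0))
        assert np.all(img == 255) and not mask.any()

    def test_deterministic(self):
        spec = SyntheticSlideSpec(image_size=(512, 512), n_blobs=1, seed=3)
        i1, m1 = generate_slide_image(spec)
        i2, m2 = generate_slide_image(spec)
        np.testing.assert_array_equal(i1, i2)
        np.testing.assert_array_equal(m1, m2)

    def test_mask_equals_ellipse_rasterization(self):
        """Mask area matches an independent per-pixel ellipse count."""
        spec = SyntheticSlideSpec(image_size=(1024, 1024), n_blobs=3, seed=5)
        img, mask = generate_slide_image(spec)
        # re-derive blob geometry from the same RNG stream
        rng = np.random.default_rng(spec.seed)
        oracle = np.zeros(spec.image_size, bool)
        yy, xx = np.mgrid[0:1024, 0:1024]
        lo, hi = spec.blob_axes_range
        for _ in range(3):
            ry = int(rng.integers(lo, hi + 1))
            rx = int(rng.integers(lo, hi + 1))
            cy = int(rng.integers(ry + 1, 1024 - ry - 1))
            cx = int(rng.integers(rx + 1, 1024 - rx - 1))
            rng.uniform(size=3)
            oracle |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 < 1.0
        assert mask.sum() == oracle.sum()
        assert np.array_equal(mask, oracle)

    def test_blob_axes_must_fit(self):
        with pytest.raises(ValueError):
            SyntheticSlideSpec(image_size=(100, 100), blob_axes_range=(60, 60))
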