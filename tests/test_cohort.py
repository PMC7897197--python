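"""Synthetic cohort generator: growth curves, phantom, series, I/O."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from t1norm import (
    CohortConfig,
    RegionSpec,
    calibrate_offset,
    default_region_table,
    frame_times,
    render_phantom,
    sample_subject,
    simulate_pixel_series,
    synthesize_series,
    true_t1,
)
from t1norm.cohort import Ellipse, HEAD_ELLIPSE, REGION_NAMES, generate_cohort


def region_with(a=800.0, r=-0.8, b=1038.0, **kw):
    defaults = dict(
        name="putamen", label=1,
        ellipses=(Ellipse("na", 110, 110, 10, 6),),
        growth_a=a, growth_r=r, growth_b=b,
    )
    defaults.update(kw)
    return RegionSpec(**defaults)


class TestGrowthCurve:
    def test_constant_region_returns_offset(self):
        reg = region_with(a=0.0, r=0.0, b=4000.0, age_independent=True)
        assert true_t1(reg, 0.3) == 4000.0 == true_t1(reg, 17.0)

    def test_unit_age_identity(self):
        assert true_t1(region_with(), 1.0) == pytest.approx(800.0 + 1038.0)

    def test_strictly_decreasing_for_default_regions(self):
        ages = np.linspace(0.05, 18, 300)
        for reg in default_region_table():
            if reg.age_independent:
                continue
            vals = true_t1(reg, ages)
            assert np.all(np.diff(vals) < 0), reg.name

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            true_t1(region_with(), 0.0)


class TestCalibrateOffset:
    def test_zero_amplitude_passthrough(self):
        assert calibrate_offset(0.0, -0.8, 1162.0) == 1162.0

    def test_matches_quadrature_oracle(self):
        # independent oracle: numerical integration of a*x^r over [5, 18]
        for a, r in [(800.0, -0.8), (350.0, -0.4), (500.0, -1.0), (300.0, -0.6)]:
            mean_term = quad(lambda x: a * x**r, 5, 18)[0] / 13.0
            assert calibrate_offset(a, r, 1162.0) == pytest.approx(
                1162.0 - mean_term, abs=1e-9
            )

    def test_printed_example_values(self):
        # 800 x^-0.8 has mean ~124.0 over [5, 18]
        assert calibrate_offset(800.0, -0.8, 1162.0) == pytest.approx(1038.0, abs=0.1)

    def test_calibrated_region_hits_pooled_target_on_dense_grid(self):
        a, r, target = 350.0, -0.4, 1162.0
        b = calibrate_offset(a, r, target)
        reg = region_with(a=a, r=r, b=b)
        ages = np.linspace(5, 18, 2_000_001)  # midpoint-free dense grid
        pooled = np.trapezoid(true_t1(reg, ages), ages) / 13.0
        assert pooled == pytest.approx(target, abs=1e-4)

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(ValueError):
            calibrate_offset(5000.0, -0.8, 100.0)


class TestDefaultRegionTable:
    def test_nine_uniquely_labeled_regions(self):
        table = default_region_table()
        assert tuple(r.name for r in table) == REGION_NAMES
        assert len({r.label for r in table}) == 9

    def test_anchored_regions_match_published_pooled_values(self):
        pooled = {
            "frontal_white_matter": 758.0,
            "thalamus": 1101.0,
            "putamen": 1162.0,
            "caudate_nucleus": 1272.0,
        }
        ages = np.linspace(5, 18, 100_001)
        for reg in default_region_table():
            if reg.name in pooled:
                assert reg.anchored
                mean = np.trapezoid(true_t1(reg, ages), ages) / 13.0
                assert mean == pytest.approx(pooled[reg.name], abs=0.01)

    def test_only_bulbus_is_age_independent(self):
        flags = {r.name: r.age_independent for r in default_region_table()}
        assert flags.pop("bulbus_oculi") is True
        assert not any(flags.values())


class TestSampleSubject:
    def test_zero_cv_lands_exactly_on_growth_curve(self):
        regions = tuple(
            RegionSpec(**{**r.__dict__, "between_subject_cv": 0.0})
            for r in default_region_table()
        )
        cfg = CohortConfig(n_subjects=3, regions=regions, master_seed=1)
        s = sample_subject(cfg, 0)
        for reg in regions:
            assert s.true_t1_by_region[reg.name] == pytest.approx(
                true_t1(reg, s.age_years)
            )

    def test_deterministic_given_seed_and_index(self):
        cfg = CohortConfig(master_seed=9)
        assert sample_subject(cfg, 5) == sample_subject(cfg, 5)
        assert sample_subject(cfg, 5) != sample_subject(cfg, 6)

    def test_ages_within_cohort_range(self):
        cfg = CohortConfig(n_subjects=50, master_seed=3)
        ages = [sample_subject(cfg, i).age_years for i in range(50)]
        assert min(ages) >= 0.17 and max(ages) <= 18.0

    def test_log_uniform_sampling_skews_young(self):
        young = CohortConfig(n_subjects=60, age_sampling="log_uniform", master_seed=3)
        flat = CohortConfig(n_subjects=60, master_seed=3)
        mean_young = np.mean([sample_subject(young, i).age_years for i in range(60)])
        mean_flat = np.mean([sample_subject(flat, i).age_years for i in range(60)])
        assert mean_young < mean_flat

    def test_empirical_cv_matches_configured_cv(self):
        # Monte-Carlo: fixed age, many subjects, putamen cv 0.024
        cfg = CohortConfig(
            n_subjects=10_000, age_sampling="from_list", ages=(8.0,), master_seed=7
        )
        vals = np.array(
            [sample_subject(cfg, i).true_t1_by_region["putamen"] for i in range(10_000)]
        )
        cv = vals.std() / vals.mean()
        target = cfg.region("putamen").between_subject_cv
        se = target / np.sqrt(2 * 10_000)
        assert abs(cv - target) < 3 * se


class TestRenderPhantom:
    def test_ellipse_pixel_count_matches_area(self):
        # brute-force rasterization oracle: pi * a * b within 5%
        mask = Ellipse("na", 110, 110, 10, 6).mask()
        assert abs(mask.sum() - np.pi * 60) / (np.pi * 60) < 0.05

    def test_truth_map_carries_subject_t1_and_labels_consistent(self, small_cohort_cfg):
        cfg = small_cohort_cfg
        s = sample_subject(cfg, 0)
        labels, truth, m0 = render_phantom(s, cfg.regions, cfg)
        putamen = cfg.region("putamen")
        sel = labels == putamen.label
        assert np.all(truth[sel] == s.true_t1_by_region["putamen"])
        # background label 0 nowhere inside any ellipse
        for reg in cfg.regions:
            for ell in reg.ellipses:
                assert np.all(labels[ell.mask()] == reg.label)

    def test_background_and_air_compartments(self, small_cohort_cfg):
        cfg = small_cohort_cfg
        s = sample_subject(cfg, 0)
        labels, truth, m0 = render_phantom(s, cfg.regions, cfg)
        head = Ellipse("na", *HEAD_ELLIPSE[0:2], *HEAD_ELLIPSE[2:4]).mask()
        assert np.all(m0[~head] == 0)
        bg = head & (labels == 0)
        assert np.all(truth[bg] == cfg.background_t1)
        assert np.all(m0[bg] == cfg.background_m0)

    def test_overlapping_regions_rejected(self, small_cohort_cfg):
        cfg = small_cohort_cfg
        s = sample_subject(cfg, 0)
        clash = list(default_region_table())
        clash[1] = RegionSpec(
            **{**clash[1].__dict__, "ellipses": clash[0].ellipses}
        )
        with pytest.raises(ValueError, match="overlap"):
            render_phantom(s, tuple(clash), cfg)


class TestSynthesizeSeries:
    def test_noise_free_pixels_follow_forward_model(self, protocol):
        cfg = CohortConfig(n_subjects=1, pixel_noise_sd=0.0, master_seed=2)
        s = sample_subject(cfg, 0)
        labels, truth, m0 = render_phantom(s, cfg.regions, cfg)
        stack = synthesize_series(s, protocol, cfg)
        assert stack.shape == (67, 220, 220)
        rr, cc = np.nonzero(labels == cfg.region("thalamus").label)
        expected = simulate_pixel_series(
            s.true_t1_by_region["thalamus"], 1000.0, protocol
        )
        np.testing.assert_allclose(stack[:, rr[0], cc[0]], expected, rtol=1e-12)
        assert np.all(stack[:, ~(m0 > 0)] == 0)

    def test_seeded_series_bit_identical(self, protocol, small_cohort_cfg):
        s = sample_subject(small_cohort_cfg, 1)
        a = synthesize_series(s, protocol, small_cohort_cfg)
        b = synthesize_series(s, protocol, small_cohort_cfg)
        np.testing.assert_array_equal(a, b)


class TestGenerateCohort:
    def test_writes_series_labels_truth_and_manifest(self, tmp_path, protocol):
        cfg = CohortConfig(n_subjects=3, master_seed=4)
        manifest = generate_cohort(cfg, protocol, tmp_path)
        assert len(list(tmp_path.glob("*_series.nii"))) == 3
        assert len(list(tmp_path.glob("*_labels.nii"))) == 3
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert len(truth) == 27  # 3 subjects x 9 regions
        assert truth.age_years.between(0.17, 18.0).all()
        echoed = json.loads((tmp_path / "manifest.json").read_text())
        assert echoed["master_seed"] == 4

    def test_same_seed_reproduces_identical_truth_table(self, tmp_path, protocol):
        cfg = CohortConfig(n_subjects=2, master_seed=6)
        generate_cohort(cfg, protocol, tmp_path / "a")
        generate_cohort(cfg, protocol, tmp_path / "b")
        assert (tmp_path / "a/truth.csv").read_text() == (
            tmp_path / "b/truth.csv"
        ).read_text()
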