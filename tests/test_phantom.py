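"""Phantom geometry, cycle simulation, and cohort generation tests."""

import dataclasses

import numpy as np
import pytest

from mammocycle.cyclestats import coefficient_of_variation, spearman_r
from mammocycle.errors import ConfigurationError
from mammocycle.phantom import (
    CohortSpec,
    CycleModel,
    DEFAULT_TIMEPOINTS,
    PhantomSpec,
    build_phantom,
    luteal_bump,
    measurement_cv_for_target,
    render_series_to_volumes,
    simulate_breast_series,
    simulate_cohort,
)
from mammocycle.segmentation import Tissue
from mammocycle.volumetry import cohort_to_frame, compute_volumetrics


class TestPhantomSpec:
    def test_tissue_ordering_enforced(self):
        with pytest.raises(ValueError):
            PhantomSpec(sos_gland=1600.0, sos_duct=1515.0)
        with pytest.raises(ValueError):
            PhantomSpec(sos_skin=1400.0)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            PhantomSpec(gland_fraction=0.7, duct_fraction=0.5)
        with pytest.raises(ValueError):
            PhantomSpec(gland_fraction=-0.1)

    def test_grid_must_contain_breast(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(grid_shape=(32, 32, 32), breast_radius_mm=55.0)


class TestBuildPhantom:
    def test_zero_radius_is_all_water(self):
        spec = PhantomSpec(breast_radius_mm=0.0, skin_thickness_mm=0.0)
        vol, labels = build_phantom(spec, seed=0)
        assert np.all(labels.labels == Tissue.WATER)
        assert np.all(vol.values == spec.sos_water)

    def test_ground_truth_fractions_match_spec(self, small_spec, small_phantom):
        _, gt = small_phantom
        n_breast = np.count_nonzero(gt.labels != Tissue.WATER)
        gland = gt.count(Tissue.GLAND) / n_breast
        duct = gt.count(Tissue.DUCT) / n_breast
        assert gland == pytest.approx(small_spec.gland_fraction, rel=0.10)
        assert duct == pytest.approx(small_spec.duct_fraction, rel=0.10)

    def test_sos_ordering_of_ground_truth_tissues(self, small_spec):
        spec = dataclasses.replace(small_spec, sos_noise_sd=6.0)
        vol, gt = build_phantom(spec, seed=9)
        v = vol.values
        assert v[gt.labels == Tissue.DUCT].mean() \
            > v[gt.labels == Tissue.GLAND].mean() \
            > v[gt.labels == Tissue.FAT].mean()

    def test_noiseless_phantom_has_one_sos_value_per_label(self, small_phantom):
        vol, gt = small_phantom
        for tissue in Tissue:
            sel = gt.labels == tissue
            if sel.any():
                assert np.unique(vol.values[sel]).size == 1

    def test_determinism(self, small_spec):
        v1, l1 = build_phantom(small_spec, seed=42)
        v2, l2 = build_phantom(small_spec, seed=42)
        v3, _ = build_phantom(dataclasses.replace(small_spec, sos_noise_sd=3.0), seed=1)
        v4, _ = build_phantom(dataclasses.replace(small_spec, sos_noise_sd=3.0), seed=2)
        assert np.array_equal(v1.values, v2.values)
        assert np.array_equal(l1.labels, l2.labels)
        assert not np.array_equal(v3.values, v4.values)

    def test_overfull_breast_rejected(self, small_spec):
        spec = dataclasses.replace(small_spec, gland_fraction=0.8, duct_fraction=0.15)
        with pytest.raises(ConfigurationError):
            build_phantom(spec, seed=0)


class TestLutealBump:
    def test_zero_at_menses_onset_and_peak_at_luteal_day(self):
        assert luteal_bump(0.0) == 0.0
        assert luteal_bump(28.0) == 0.0
        assert luteal_bump(24.0) == 1.0

    def test_supported_only_in_late_luteal_window(self):
        t = np.arange(0.0, 28.0, 0.5)
        b = luteal_bump(t)
        assert np.all(b[(t < 20.0) | (t > 28.0)] == 0.0)
        assert b.max() == 1.0


class TestSimulateBreastSeries:
    def test_no_amplitude_no_noise_is_constant(self):
        m = CycleModel(luteal_amplitude_gland=0.0, luteal_amplitude_duct=0.0,
                       measurement_noise_cv=0.0)
        s = simulate_breast_series(m, "pre", [0, 7, 14, 21], seed=0)
        assert coefficient_of_variation(s.values("gland")).cov == 0.0
        assert coefficient_of_variation(s.values("duct")).cov == 0.0

    def test_peak_lies_in_luteal_window(self):
        m = CycleModel(luteal_amplitude_gland=0.3, measurement_noise_cv=0.0)
        days = list(range(0, 28))
        s = simulate_breast_series(m, "pre", days, seed=0)
        gland = s.values("gland")
        peak_day = days[int(np.argmax(gland))]
        assert 20.0 < peak_day < 28.0  # just prior to menstruation

    def test_cov_calibration_over_many_seeds(self):
        """Monte-Carlo: the solved noise CV brings the mean series CoV to
        the configured target within sampling/bias tolerance."""
        target = 0.20
        cv = measurement_cv_for_target(target, 0.25, DEFAULT_TIMEPOINTS)
        rng = np.random.default_rng(7)
        covs = [
            coefficient_of_variation(
                simulate_breast_series(
                    CycleModel(measurement_noise_cv=cv,
                               phase_offset_days=float(rng.uniform(0, 28))),
                    "pre", DEFAULT_TIMEPOINTS, seed=i).values("gland")).cov
            for i in range(250)
        ]
        assert np.mean(covs) == pytest.approx(target, rel=0.10)

    def test_scale_invariance_of_series_cov(self):
        m1 = CycleModel(measurement_noise_cv=0.15)
        m2 = dataclasses.replace(
            m1, baseline_gland_cc=2 * m1.baseline_gland_cc,
            baseline_duct_cc=2 * m1.baseline_duct_cc,
            baseline_tbv_cc=2 * m1.baseline_tbv_cc)
        s1 = simulate_breast_series(m1, "pre", DEFAULT_TIMEPOINTS, seed=5)
        s2 = simulate_breast_series(m2, "pre", DEFAULT_TIMEPOINTS, seed=5)
        c1 = coefficient_of_variation(s1.values("gland")).cov
        c2 = coefficient_of_variation(s2.values("gland")).cov
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_invalid_timepoints_rejected(self):
        m = CycleModel()
        with pytest.raises(ValueError):
            simulate_breast_series(m, "pre", [0, 7, 7], seed=0)
        with pytest.raises(ValueError):
            simulate_breast_series(m, "pre", [0], seed=0)


class TestSimulateCohort:
    def test_bookkeeping(self):
        spec = CohortSpec(n_pre_subjects=10, n_peri_subjects=0,
                          n_post_subjects=4, seed=0)
        cohort = simulate_cohort(spec)
        assert len(cohort) == 28  # two breasts per subject
        groups = [s.group for s in cohort]
        assert groups.count("pre") == 20 and groups.count("post") == 8
        ids = {s.breast_id for s in cohort}
        assert len(ids) == 28

    def test_determinism_contract(self):
        a = cohort_to_frame(simulate_cohort(CohortSpec(seed=3)))
        b = cohort_to_frame(simulate_cohort(CohortSpec(seed=3)))
        c = cohort_to_frame(simulate_cohort(CohortSpec(seed=4)))
        assert a.equals(b)
        assert not a["gland_cc"].equals(c["gland_cc"])

    def test_zero_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_pre_subjects=0, n_peri_subjects=0, n_post_subjects=0)

    def test_gland_duct_coupling_gives_high_rank_correlation(self):
        """Default coupling: per-breast mean duct vs. gland volumes are
        strongly rank-correlated (tested at 100 breasts where the
        sampling error of Spearman r is small)."""
        spec = CohortSpec(n_pre_subjects=50, n_peri_subjects=0,
                          n_post_subjects=2, seed=0)
        df = cohort_to_frame(simulate_cohort(spec))
        pre = df[df.group == "pre"].groupby("breast_id")[
            ["gland_cc", "duct_cc"]].mean()
        r = spearman_r(pre["gland_cc"], pre["duct_cc"]).spearman_r
        assert r > 0.8

    def test_group_mean_cov_converges_to_targets(self):
        """Law-of-large-numbers check at 100 subjects per group."""
        spec = CohortSpec(n_pre_subjects=100, n_peri_subjects=0,
                          n_post_subjects=100, seed=1)
        df = cohort_to_frame(simulate_cohort(spec))
        out = {}
        for (group, breast), sub in df.groupby(["group", "breast_id"]):
            for tissue in ("gland", "duct"):
                out.setdefault((group, tissue), []).append(
                    coefficient_of_variation(sub[f"{tissue}_cc"]).cov)
        means = {k: float(np.mean(v)) for k, v in out.items()}
        assert means[("pre", "gland")] == pytest.approx(0.20, rel=0.10)
        assert means[("post", "gland")] == pytest.approx(0.125, rel=0.10)
        assert means[("pre", "duct")] == pytest.approx(0.20, rel=0.10)
        assert means[("post", "duct")] == pytest.approx(0.20, rel=0.10)


@pytest.fixture(scope="module")
def series_and_spec(small_spec):
    model = CycleModel(baseline_gland_cc=8.0, baseline_duct_cc=3.0,
                       baseline_tbv_cc=60.0, luteal_amplitude_gland=0.3,
                       luteal_amplitude_duct=0.1, measurement_noise_cv=0.0)
    series = simulate_breast_series(model, "pre", [0, 14, 24], seed=3)
    return series, small_spec


class TestRenderSeries:

    def test_one_volume_per_timepoint(self, series_and_spec):
        series, spec = series_and_spec
        single = dataclasses.replace(series, observations=series.observations[:1],
                                     excluded=[""])
        assert len(render_series_to_volumes(single, spec, seed=5)) == 1

    def test_roundtrip_recovers_series_within_voxelization(self, series_and_spec):
        series, spec = series_and_spec
        voxel_cc = spec.voxel_volume_mm3 / 1000.0
        rendered = render_series_to_volumes(series, spec, seed=5)
        for obs, (_, labels) in zip(series.observations, rendered):
            vm = compute_volumetrics(labels)
            assert abs(vm.gland_cc - obs.gland_cc) <= voxel_cc
            assert abs(vm.duct_cc - obs.duct_cc) <= voxel_cc

    def test_luteal_peak_renders_larger_gland_than_onset(self, series_and_spec):
        series, spec = series_and_spec
        rendered = render_series_to_volumes(series, spec, seed=5)
        onset = compute_volumetrics(rendered[0][1]).gland_cc
        peak = compute_volumetrics(rendered[-1][1]).gland_cc
        assert peak > onset

    def test_capacity_exceeded_rejected(self, series_and_spec):
        series, spec = series_and_spec
        huge = dataclasses.replace(
            series.observations[0], gland_cc=500.0, fat_cc=0.0,
            tbv_cc=500.0 + series.observations[0].duct_cc)
        bad = dataclasses.replace(series, observations=[huge] * 2,
                                  excluded=["", ""])
        with pytest.raises(ConfigurationError):
            render_series_to_volumes(bad, spec, seed=5)
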