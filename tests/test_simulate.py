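"""Generator contracts: seeded determinism, exact marker assignment,
Gaussian peak geometry, jitter bounds, and noise/baseline behavior."""

import numpy as np
import pytest

from vocsense import (BaselineSpec, ConfigurationError, SimulationConfig,
                      render_peak, simulate_calibration_series,
                      simulate_cohort, sensor_sensitivity)
from vocsense.cohort import CANCER
from vocsense.config import MarkerPeakSpec, PeakSpec, SecondaryEffect

from conftest import small_config


def exact_copy(cfg):
    return SimulationConfig.from_flat_dict(cfg.to_flat_dict())


def deterministic_config(**overrides):
    """Small config with every random amplitude/noise source switched off."""
    cfg = small_config(**overrides)
    return cfg.replace(
        shared_peaks=tuple(PeakSpec(p.location, p.width_sd, p.amplitude_mean,
                                    amplitude_cv=0.0)
                           for p in cfg.shared_peaks),
        marker_peak=MarkerPeakSpec(
            location=cfg.marker_peak.location,
            width_sd=cfg.marker_peak.width_sd,
            amplitude_mean=cfg.marker_peak.amplitude_mean,
            amplitude_cv=0.0,
            prevalence_cancer=cfg.marker_peak.prevalence_cancer),
        rt_jitter_frac=0.0,
        noise_sd=0.0,
        baseline=BaselineSpec(start_level=100.0, drift_sd=0.0, slope_sd=0.0))


class TestRenderPeak:
    def test_apex_at_nearest_grid_point_with_configured_amplitude(self):
        sig = render_peak(3204, width_sd=25, amplitude=1.0, grid_length=5040)
        assert np.argmax(sig) + 1 == 3204
        assert sig[3203] == pytest.approx(1.0)
        assert np.all(sig >= 0)

    def test_zero_amplitude_gives_all_zero_signal(self):
        assert not np.any(render_peak(100, 10, 0.0, 500))

    def test_full_width_at_tenth_maximum_matches_gaussian_closed_form(self):
        # FW at 10% of max for a Gaussian of SD w is 2 w sqrt(2 ln 10)
        w = 25.0
        sig = render_peak(2500, w, 1.0, 5040)
        above = np.flatnonzero(sig >= 0.1)
        fw = above[-1] - above[0] + 1
        assert abs(fw - 2 * w * np.sqrt(2 * np.log(10))) <= 1.0

    @pytest.mark.parametrize("loc,width,amp", [(0, 10, 1), (100, 0, 1),
                                               (100, 10, -1)])
    def test_invalid_geometry_rejected(self, loc, width, amp):
        with pytest.raises(ValueError):
            render_peak(loc, width, amp, 500)


class TestSimulateCohort:
    def test_identical_seed_gives_bit_identical_cohort(self):
        cfg = small_config(seed=7)
        a = simulate_cohort(cfg)
        b = simulate_cohort(exact_copy(cfg))
        assert a.sample_ids == b.sample_ids
        np.testing.assert_array_equal(a.resistance_matrix(),
                                      b.resistance_matrix())
        assert a.metadata["marker_sample_ids"] == b.metadata["marker_sample_ids"]

    def test_exact_marker_assignment_in_default_cohort(self, default_cohort):
        # prevalence 20/24 -> exactly 20 cancer carriers, 0 control carriers
        carriers = default_cohort.metadata["marker_sample_ids"]
        assert len(carriers) == 20
        by_id = {s.sample_id: s.group for s in default_cohort}
        assert all(by_id[sid] == CANCER for sid in carriers)

    def test_group_sizes_match_config(self, default_cohort):
        assert default_cohort.group_size("cancer") == 24
        assert default_cohort.group_size("control") == 74
        assert default_cohort.grid_length == 5040

    def test_noise_free_output_is_exactly_baseline_plus_rendered_peaks(self):
        cfg = deterministic_config(seed=5)
        cohort = simulate_cohort(cfg)
        carriers = set(cohort.metadata["marker_sample_ids"])
        for sample in cohort:
            expected = np.full(cfg.grid_length, 100.0)
            shifts = {e.location: e.amplitude_shift
                      for e in cfg.secondary_effects}
            for p in cfg.shared_peaks:
                amp = p.amplitude_mean
                if sample.group == CANCER and p.location in shifts:
                    amp += shifts[p.location]
                expected += render_peak(p.location, p.width_sd, amp,
                                        cfg.grid_length)
            if sample.sample_id in carriers:
                mp = cfg.marker_peak
                expected += render_peak(mp.location, mp.width_sd,
                                        mp.amplitude_mean, cfg.grid_length)
            np.testing.assert_allclose(sample.resistance, expected,
                                       atol=1e-12)

    def test_no_jitter_no_noise_apex_at_configured_location(self):
        cfg = deterministic_config(seed=2)
        cohort = simulate_cohort(cfg)
        sample = cohort.samples[0]
        # isolated marker-free region: check the well-separated 420 peak
        lo, hi = 380, 460
        apex = lo + int(np.argmax(sample.resistance[lo - 1:hi]))
        assert apex == 420

    def test_jitter_factors_bounded_by_configured_fraction(self):
        j = 0.05
        cohort = simulate_cohort(small_config(seed=11, rt_jitter_frac=j))
        factors = np.array(cohort.metadata["jitter_factors"])
        assert np.all(np.abs(factors - 1.0) <= j)
        # displacement of every peak center is then <= j * location

    def test_doubling_noise_sd_doubles_residual_sd(self):
        base = deterministic_config(seed=9)
        clean = simulate_cohort(base).resistance_matrix()
        lo = simulate_cohort(base.replace(noise_sd=0.05)).resistance_matrix()
        hi = simulate_cohort(base.replace(noise_sd=0.10)).resistance_matrix()
        sd_lo = (lo - clean).std()
        sd_hi = (hi - clean).std()
        assert sd_hi / sd_lo == pytest.approx(2.0, rel=1e-6)
        assert sd_lo == pytest.approx(0.05, rel=0.05)

    @pytest.mark.parametrize("field,value", [
        ("n_cancer", 0), ("n_control", -1), ("rt_jitter_frac", -0.1),
        ("noise_sd", -1.0),
    ])
    def test_invalid_config_names_offending_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            small_config(**{field: value})

    def test_marker_outside_grid_rejected(self):
        with pytest.raises(ConfigurationError, match="location"):
            small_config(marker_peak=MarkerPeakSpec(location=9999.0))

    def test_secondary_effect_must_sit_on_a_shared_peak(self):
        with pytest.raises(ConfigurationError, match="secondary_effects"):
            small_config(secondary_effects=(SecondaryEffect(333.0, 1.0),))


class TestCalibrationSeries:
    def test_degenerate_distributions_echo_config(self):
        cfg = small_config(seed=1, noise_sd=0.0,
                           ethanol_rt_sd=0.0, sensitivity_sd=0.0,
                           baseline=BaselineSpec(100.0, 0.0, 0.0),
                           ethanol_rt_mean=329.2)
        run, = simulate_calibration_series(cfg, n_days=1)
        assert run.detected_rt == 329  # 329.2 snapped to the grid
        assert sensor_sensitivity(run.r0, run.rg) == pytest.approx(98.5)

    def test_seeded_series_reproducible(self):
        cfg = small_config(seed=4)
        a = simulate_calibration_series(cfg, 20)
        b = simulate_calibration_series(exact_copy(cfg), 20)
        assert a == b

    def test_sample_mean_rt_within_one_se_band_of_configured_mean(self):
        cfg = SimulationConfig(seed=2)
        runs = simulate_calibration_series(cfg, 150)
        rts = np.array([r.detected_rt for r in runs], dtype=float)
        se = cfg.ethanol_rt_sd / np.sqrt(len(rts))
        # CLT check at the configured spread; 3 SE keeps flake risk tiny
        assert abs(rts.mean() - cfg.ethanol_rt_mean) <= 3 * se

    def test_rejects_empty_series(self):
        with pytest.raises(ValueError):
            simulate_calibration_series(small_config(), n_days=0)
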