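"""Seeded synthetic chromatogram and calibration-run generator.

Emulates the GC/metal-oxide-sensor instrument: Gaussian elution peaks on
the 5040-point half-second grid, a cancer-marker peak near index 3204
carried by an exact subset of the cancer group, weak group-differential
amplitude shifts at eight earlier time points, one multiplicative
retention-time jitter factor per run, per-run baseline level drift with a
gentle within-run slope, and additive measurement noise.  Identical seeds
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CANCER, CONTROL, Chromatogram, Cohort
from .config import ConfigurationError, SimulationConfig, validate_config

#: amplitude draws are truncated below at this fraction of the mean so the
#: response trace stays positive
_AMPLITUDE_FLOOR_FRAC = 0.05


def render_peak(location: float, width_sd: float, amplitude: float,
                grid_length: int) -> np.ndarray:
    """Render one Gaussian peak on the 1-based half-second grid.

    The returned signal is unimodal and non-negative with its maximum at
    the grid point nearest ``location``, where it equals ``amplitude``
    exactly (the Gaussian is evaluated relative to the snapped apex so the
    peak height does not depend on where the true center falls between
    grid points).
    """
    if not 1 <= location <= grid_length:
        raise ValueError(f"peak location {location} outside grid "
                         f"[1, {grid_length}]")
    if width_sd <= 0:
        raise ValueError("width_sd must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    apex = round(location)
    t = np.arange(1, grid_length + 1, dtype=float)
    return amplitude * np.exp(-0.5 * ((t - apex) / width_sd) ** 2)


def _draw_amplitude(rng: np.random.Generator, mean: float, cv: float) -> float:
    amp = mean * (1.0 + cv * rng.standard_normal())
    return max(amp, _AMPLITUDE_FLOOR_FRAC * mean)


def _marker_assignment(rng: np.random.Generator, n: int,
                       prevalence: float) -> np.ndarray:
    """Exact without-replacement assignment: round(prevalence * n) carriers."""
    n_carriers = int(round(prevalence * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=n_carriers, replace=False)] = True
    return mask


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one labeled cohort of synthetic chromatograms.

    Cancer samples come first (run order interleaves the groups so run-date
    is not confounded with group).  The ground-truth marker assignment and
    per-run jitter factors are recorded in ``cohort.metadata``.
    """
    validate_config(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_cancer + config.n_control
    shifts = {e.location: e.amplitude_shift for e in config.secondary_effects}

    marker_cancer = _marker_assignment(rng, config.n_cancer,
                                       config.marker_peak.prevalence_cancer)
    marker_control = _marker_assignment(rng, config.n_control,
                                        config.marker_peak.prevalence_control)

    groups = [CANCER] * config.n_cancer + [CONTROL] * config.n_control
    has_marker = np.concatenate([marker_cancer, marker_control])
    # interleave run order across groups, deterministically from the seed
    run_order = rng.permutation(n)

    jitter = rng.uniform(1.0 - config.rt_jitter_frac,
                         1.0 + config.rt_jitter_frac, size=n)
    base_levels = (config.baseline.start_level
                   + config.baseline.drift_sd * rng.standard_normal(n))
    base_levels = np.maximum(base_levels, 0.1 * config.baseline.start_level)
    slopes = config.baseline.slope_sd * rng.standard_normal(n)

    def jittered(location: float, factor: float) -> float:
        # displaced center, kept on the grid at extreme jitter settings
        return float(np.clip(location * factor, 1, config.grid_length))

    t = np.arange(config.grid_length, dtype=float)
    samples = []
    marker_ids = []
    for i in range(n):
        group = groups[i]
        signal = base_levels[i] + slopes[i] * t
        for peak in config.shared_peaks:
            mean = peak.amplitude_mean
            if group == CANCER and peak.location in shifts:
                mean = max(mean + shifts[peak.location], 0.0)
            amp = _draw_amplitude(rng, mean, peak.amplitude_cv)
            signal = signal + render_peak(jittered(peak.location, jitter[i]),
                                          peak.width_sd, amp,
                                          config.grid_length)
        mp = config.marker_peak
        # marker amplitude is drawn for every sample to keep the random
        # stream independent of the assignment
        marker_amp = _draw_amplitude(rng, mp.amplitude_mean, mp.amplitude_cv)
        if has_marker[i]:
            signal = signal + render_peak(jittered(mp.location, jitter[i]),
                                          mp.width_sd, marker_amp,
                                          config.grid_length)
        if config.noise_sd > 0:
            signal = signal + config.noise_sd * rng.standard_normal(
                config.grid_length)
        sample_id = f"{group[:3]}-{i:03d}"
        if has_marker[i]:
            marker_ids.append(sample_id)
        samples.append(Chromatogram(sample_id=sample_id, group=group,
                                    resistance=np.maximum(signal, 1e-6),
                                    run_index=int(run_order[i])))

    return Cohort(samples, metadata={
        "seed": config.seed,
        "config_fingerprint": config.fingerprint(),
        "marker_sample_ids": marker_ids,
        "jitter_factors": jitter.tolist(),
    })


@dataclass(frozen=True)
class CalibrationRun:
    """One daily ethanol-standard injection.

    ``r0`` is the baseline sensor resistance, ``rg`` the resistance under
    ethanol exposure; sensitivity in percent is ``100 * (r0 - rg) / r0``.
    ``detected_rt`` is the ethanol apex recovered by peak detection from
    the simulated calibration chromatogram.
    """

    day_index: int
    detected_rt: int
    r0: float
    rg: float

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")
        if not 0 < self.rg <= self.r0:
            raise ValueError("rg must lie in (0, r0]")


def simulate_calibration_series(config: SimulationConfig,
                                n_days: int) -> list[CalibrationRun]:
    """Simulate ``n_days`` daily ethanol calibration injections.

    Each day draws a true retention time about ``ethanol_rt_mean`` (spread
    ``ethanol_rt_sd``), renders the ethanol peak on the grid with baseline
    and noise, and recovers the apex with a peak search in a window about
    the nominal retention time.  Sensitivity draws about
    ``sensitivity_mean`` set the (r0, rg) pair; draws are clipped into
    (0, 100) so the resistance pair stays physical.
    """
    from .preprocess import detect_peak_in_trace

    validate_config(config)
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x0CA1]))
    runs = []
    half_window = max(int(10 * config.ethanol_rt_sd), 12)
    for day in range(n_days):
        true_rt = (config.ethanol_rt_mean
                   + config.ethanol_rt_sd * rng.standard_normal())
        true_rt = float(np.clip(true_rt, 1, config.grid_length))
        r0 = max(config.baseline.start_level
                 + config.baseline.drift_sd * rng.standard_normal(),
                 0.1 * config.baseline.start_level)
        trace = r0 + render_peak(true_rt, width_sd=20.0, amplitude=10.0,
                                 grid_length=config.grid_length)
        if config.noise_sd > 0:
            trace = trace + config.noise_sd * rng.standard_normal(
                config.grid_length)
        lo = max(1, int(config.ethanol_rt_mean) - half_window)
        hi = min(config.grid_length, int(config.ethanol_rt_mean) + half_window)
        detected = detect_peak_in_trace(trace, (lo, hi))
        sens = config.sensitivity_mean
        if config.sensitivity_sd > 0:
            sens = sens + config.sensitivity_sd * rng.standard_normal()
        sens = float(np.clip(sens, 0.01, 99.99))
        rg = r0 * (1.0 - sens / 100.0)
        runs.append(CalibrationRun(day_index=day, detected_rt=detected,
                                   r0=r0, rg=rg))
    return runs
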