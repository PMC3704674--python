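"""Profile standardization, group means, peak detection and QC summaries.

Both classification methods work on standardized resistance profiles: each
trace is rescaled to mean 0 and sample standard deviation 1 so donors are
comparable irrespective of baseline level and sensor gain, while the
relative minima and maxima within each profile are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .cohort import Chromatogram, Cohort, GROUPS

#: default marker-peak search window (half-second indices, 1-based,
#: inclusive), centered on the cancer-associated feature near index 3200
MARKER_WINDOW = (3100, 3300)


@dataclass
class StandardizedProfile:
    """A chromatogram rescaled to mean 0, sample SD 1 (n-1 denominator)."""

    sample_id: str
    values: np.ndarray
    source: Chromatogram | None = None

    @property
    def grid_length(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PeakCall:
    """Result of a windowed peak search on a standardized profile."""

    location: int            # half-second index of the apex (1-based)
    height: float            # response above the window's median level
    window: tuple[int, int]  # (lo, hi) half-second indices searched
    measurable: bool


def standardize(raw: Chromatogram) -> StandardizedProfile:
    """Rescale one resistance trace to mean 0 and sample SD 1.

    Idempotent, and invariant under positive affine transforms of the
    input.  A constant trace has no scale and is rejected.
    """
    x = np.asarray(raw.resistance, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"constant trace (zero variance) in sample "
                         f"{raw.sample_id}")
    return StandardizedProfile(sample_id=raw.sample_id,
                               values=(x - x.mean()) / sd, source=raw)


def standardize_cohort(cohort: Cohort) -> np.ndarray:
    """Stack the cohort's standardized profiles as an (n, grid) matrix."""
    return np.stack([standardize(s).values for s in cohort])


def group_mean_profile(cohort: Cohort, group: str) -> np.ndarray:
    """Pointwise mean of the group's standardized profiles."""
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    idx = cohort.group_indices(group)
    if len(idx) == 0:
        raise ValueError(f"group {group!r} is empty")
    return np.mean([standardize(cohort.samples[i]).values for i in idx],
                   axis=0)


def noise_scale(values: np.ndarray) -> float:
    """Robust point-noise scale from first differences.

    The median absolute deviation of the first differences, rescaled to
    the SD of the underlying iid noise (differencing doubles the variance,
    and the usual 1.4826 factor makes the MAD consistent for a Gaussian).
    """
    d = np.diff(np.asarray(values, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def detect_peak(profile: StandardizedProfile,
                window: tuple[int, int] = MARKER_WINDOW,
                min_height: float | None = None,
                smooth_window: int = 21) -> PeakCall:
    """Search a retention-time window for a measurable peak.

    A peak is *measurable* when a local maximum inside the window stands
    at least ``min_height`` above the window's median level.  The default
    ``min_height`` is 3x the profile's robust noise scale.  The apex
    search runs on a lightly smoothed copy of the window (boxcar,
    ``smooth_window`` points — far narrower than the ~100-point
    chromatographic peaks) so that single-point noise excursions do not
    register as peaks; height is read from the smoothed trace.
    """
    lo, hi = int(window[0]), int(window[1])
    n = profile.grid_length
    if not (1 <= lo < hi <= n):
        raise ValueError(f"window {window} invalid for grid of length {n}")
    if min_height is None:
        min_height = 3.0 * noise_scale(profile.values)
    if min_height < 0:
        raise ValueError("min_height must be >= 0")

    segment = _smooth(np.asarray(profile.values, dtype=float), smooth_window)
    segment = segment[lo - 1:hi]  # 1-based inclusive window
    baseline = float(np.median(segment))
    peaks, _ = find_peaks(segment)
    if len(peaks) == 0:
        return PeakCall(location=lo, height=0.0, window=(lo, hi),
                        measurable=False)
    apex_rel = peaks[np.argmax(segment[peaks])]
    height = float(segment[apex_rel] - baseline)
    return PeakCall(location=lo + int(apex_rel), height=height,
                    window=(lo, hi), measurable=height >= min_height)


def detect_peak_in_trace(trace: np.ndarray, window: tuple[int, int],
                         smooth_window: int = 9) -> int:
    """Apex half-second index of the largest value inside a raw-trace window.

    Used for calibration-run retention-time recovery, where exactly one
    peak is expected in the window; returns the (smoothed) argmax.
    """
    lo, hi = int(window[0]), int(window[1])
    if not (1 <= lo < hi <= len(trace)):
        raise ValueError(f"window {window} invalid for trace of length "
                         f"{len(trace)}")
    segment = _smooth(np.asarray(trace, dtype=float), smooth_window)[lo - 1:hi]
    return lo + int(np.argmax(segment))


def assess_rt_stability(peak_tracks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-peak retention-time stability across runs.

    ``peak_tracks`` maps a peak name to the sequence of detected apex
    locations across runs.  Returns one row per peak with the mean, SD
    (n-1) and maximum fractional deviation ``max |loc - mean| / mean``.
    """
    rows = []
    for name, track in peak_tracks.items():
        arr = np.asarray(track, dtype=float)
        if arr.size == 0:
            raise ValueError(f"empty track {name!r}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite entries in track {name!r}")
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        max_dev = float(np.max(np.abs(arr - mean)) / mean) if mean else np.inf
        rows.append({"peak": name, "n_runs": arr.size, "mean_rt": mean,
                     "sd_rt": sd, "max_fractional_deviation": max_dev})
    return pd.DataFrame(rows)


def sensor_sensitivity(r0: float, rg: float) -> float:
    """Sensor sensitivity percentage, 100 * (R0 - Rg) / R0.

    ``r0`` is the baseline resistance and ``rg`` the resistance under
    analyte exposure; a complete resistance drop gives 100%.
    """
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    if rg < 0:
        raise ValueError("rg must be >= 0")
    return 100.0 * (r0 - rg) / r0
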