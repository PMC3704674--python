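"""Parameterization of the simulated GC/metal-oxide-sensor instrument.

A :class:`SimulationConfig` fully describes one synthetic study: cohort
sizes, the shared chromatographic peak library, the cancer-marker peak,
weak group-differential amplitude shifts, per-run retention-time jitter,
baseline drift, measurement noise, and the daily ethanol calibration
distributions.  Everything the generator draws is governed by the single
integer ``seed``.

Time is indexed on the instrument's half-second grid: ``t = 1 .. 5040``
(42 minutes at 0.5 s per point).  Peak locations, widths and retention
times are all expressed in half-second grid units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence


class ConfigurationError(ValueError):
    """An invalid simulation parameter; the message names the field."""


@dataclass(frozen=True)
class PeakSpec:
    """One chromatographic peak shared by both groups.

    ``location`` is the apex half-second index (1-based); ``width_sd`` the
    Gaussian width in half-seconds; per-sample amplitudes are drawn as
    ``amplitude_mean * (1 + amplitude_cv * z)`` with ``z ~ N(0, 1)``,
    truncated below at 5% of the mean so resistance responses stay positive.
    """

    location: float
    width_sd: float
    amplitude_mean: float
    amplitude_cv: float = 0.15


@dataclass(frozen=True)
class MarkerPeakSpec:
    """The cancer-associated peak near half-second index 3200.

    ``prevalence_cancer`` / ``prevalence_control`` give the fraction of each
    group that carries the peak; the generator assigns it to an exact
    ``round(prevalence * n)`` subset (without replacement) so the count is
    deterministic.
    """

    location: float = 3204.0
    width_sd: float = 30.0
    amplitude_mean: float = 8.0
    amplitude_cv: float = 0.25
    prevalence_cancer: float = 20.0 / 24.0
    prevalence_control: float = 0.0


@dataclass(frozen=True)
class SecondaryEffect:
    """A weak group-differential amplitude shift at one shared-peak apex.

    ``amplitude_shift`` is added to the shared peak's mean amplitude for
    cancer samples only (cancer minus control difference; may be negative).
    The shift magnitudes are calibration constants of the disease model,
    not physical measurements.
    """

    location: float
    amplitude_shift: float


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline-resistance model: per-run level drift plus within-run slope.

    Each run's baseline level is ``start_level + N(0, drift_sd)`` and a
    gentle linear slope ``N(0, slope_sd)`` (resistance units per grid point)
    is added across the run.
    """

    start_level: float = 100.0
    drift_sd: float = 5.0
    slope_sd: float = 0.0005


def _default_shared_peaks() -> tuple[PeakSpec, ...]:
    # Peak widths grow with retention time: full width at 10% of maximum
    # ~4.29*width_sd, i.e. ~80 half-seconds early rising to ~190 late.
    locations = (117, 153, 174, 201, 359, 520, 760, 1073, 1162, 1362,
                 1700, 2200, 2700, 3600, 4100, 4600)
    amplitudes = (9.0, 7.5, 8.5, 10.0, 12.0, 6.0, 5.0, 9.0, 8.0, 10.0,
                  6.5, 5.5, 4.5, 5.0, 4.0, 3.5)
    return tuple(
        PeakSpec(location=float(loc),
                 width_sd=18.0 + 27.0 * loc / 5040.0,
                 amplitude_mean=amp)
        for loc, amp in zip(locations, amplitudes)
    )


def _default_secondary_effects() -> tuple[SecondaryEffect, ...]:
    # Calibration constants: shift magnitudes chosen so the end-to-end
    # pipelines reach the documented leave-one-out error rates on default
    # cohorts.  Locations are the eight early/mid informative time points.
    shifts = {
        117: 3.5,
        153: -2.9,
        174: 4.0,
        201: -3.5,
        359: 4.4,
        1073: 3.3,
        1162: -3.3,
        1362: 2.9,
    }
    return tuple(SecondaryEffect(float(k), v) for k, v in shifts.items())


@dataclass(frozen=True)
class SimulationConfig:
    n_cancer: int = 24
    n_control: int = 74
    grid_length: int = 5040
    sampling_interval: float = 0.5
    shared_peaks: tuple[PeakSpec, ...] = field(default_factory=_default_shared_peaks)
    marker_peak: MarkerPeakSpec = field(default_factory=MarkerPeakSpec)
    secondary_effects: tuple[SecondaryEffect, ...] = field(
        default_factory=_default_secondary_effects)
    rt_jitter_frac: float = 0.01
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    noise_sd: float = 0.05
    ethanol_rt_mean: float = 329.2
    ethanol_rt_sd: float = 3.97
    sensitivity_mean: float = 98.5
    sensitivity_sd: float = 10.6
    seed: int = 0

    def __post_init__(self) -> None:
        validate_config(self)

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    # -- provenance ---------------------------------------------------

    def fingerprint(self) -> str:
        """Short stable hash of every parameter, for artifact provenance."""
        import hashlib
        import json

        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- flat key-value form ------------------------------------------

    def to_flat_dict(self) -> dict[str, str]:
        """Flatten to dotted string keys (``shared_peaks.0.location`` ...)."""
        flat: dict[str, str] = {}

        def walk(prefix: str, obj) -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(f"{prefix}.{i}", v)
            else:
                flat[prefix] = repr(obj)

        walk("", asdict(self))
        return flat

    @classmethod
    def from_flat_dict(cls, flat: dict[str, str]) -> "SimulationConfig":
        import ast

        nested: dict = {}
        for key, raw in flat.items():
            parts = key.split(".")
            node = nested
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = ast.literal_eval(raw)

        def as_seq(node: dict) -> list:
            return [node[k] for k in sorted(node, key=int)]

        kwargs = dict(nested)
        if "shared_peaks" in kwargs:
            kwargs["shared_peaks"] = tuple(
                PeakSpec(**d) for d in as_seq(kwargs["shared_peaks"]))
        if "secondary_effects" in kwargs:
            kwargs["secondary_effects"] = tuple(
                SecondaryEffect(**d) for d in as_seq(kwargs["secondary_effects"]))
        if "marker_peak" in kwargs:
            kwargs["marker_peak"] = MarkerPeakSpec(**kwargs["marker_peak"])
        if "baseline" in kwargs:
            kwargs["baseline"] = BaselineSpec(**kwargs["baseline"])
        return cls(**kwargs)


def validate_config(config: SimulationConfig) -> None:
    """Raise :class:`ConfigurationError` naming the first offending field."""
    if config.n_cancer <= 0:
        raise ConfigurationError("n_cancer must be > 0")
    if config.n_control <= 0:
        raise ConfigurationError("n_control must be > 0")
    if config.grid_length <= 1:
        raise ConfigurationError("grid_length must be > 1")
    if config.sampling_interval <= 0:
        raise ConfigurationError("sampling_interval must be > 0")
    if config.rt_jitter_frac < 0:
        raise ConfigurationError("rt_jitter_frac must be >= 0")
    if config.noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if config.ethanol_rt_sd < 0:
        raise ConfigurationError("ethanol_rt_sd must be >= 0")
    if config.sensitivity_sd < 0:
        raise ConfigurationError("sensitivity_sd must be >= 0")
    if config.baseline.start_level <= 0:
        raise ConfigurationError("baseline.start_level must be > 0")
    mp = config.marker_peak
    for name, prev in (("prevalence_cancer", mp.prevalence_cancer),
                       ("prevalence_control", mp.prevalence_control)):
        if not 0.0 <= prev <= 1.0:
            raise ConfigurationError(f"marker_peak.{name} must lie in [0, 1]")
    peaks = list(config.shared_peaks) + [mp]
    for peak in peaks:
        if not 1 <= peak.location <= config.grid_length:
            raise ConfigurationError(
                f"peak location {peak.location} outside grid "
                f"[1, {config.grid_length}]")
        if peak.width_sd <= 0:
            raise ConfigurationError(f"peak width_sd must be > 0 "
                                     f"(location {peak.location})")
        if peak.amplitude_mean < 0:
            raise ConfigurationError(f"peak amplitude_mean must be >= 0 "
                                     f"(location {peak.location})")
    shared_locs = {p.location for p in config.shared_peaks}
    for eff in config.secondary_effects:
        if eff.location not in shared_locs:
            raise ConfigurationError(
                f"secondary_effects location {eff.location} does not match "
                "any shared peak apex")
    if not 1 <= config.ethanol_rt_mean <= config.grid_length:
        raise ConfigurationError("ethanol_rt_mean outside grid")
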