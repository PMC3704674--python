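"""In-memory containers for chromatogram cohorts.

A :class:`Chromatogram` is one sample's raw sensor response on the fixed
half-second grid (peaks are maxima: the generator and readers use the
already-inverted "response" sign convention, since a metal-oxide sensor
responds to a volatile with a resistance *drop*).  A :class:`Cohort` is a
labeled collection of chromatograms on a common grid with a feature-matrix
view used by the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

CANCER = "cancer"
CONTROL = "control"
GROUPS = (CANCER, CONTROL)


@dataclass
class Chromatogram:
    sample_id: str
    group: str
    resistance: np.ndarray  # raw positive response trace, length grid_length
    run_index: int

    def __post_init__(self) -> None:
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        if self.resistance.ndim != 1:
            raise ValueError("resistance trace must be one-dimensional")
        if not np.all(np.isfinite(self.resistance)):
            raise ValueError(f"non-finite resistance in sample {self.sample_id}")
        if np.any(self.resistance <= 0):
            raise ValueError(f"non-positive resistance in sample {self.sample_id}")


@dataclass
class Cohort:
    """Two-group collection of chromatograms on a common grid.

    ``metadata`` carries generator provenance (seed, config fingerprint and
    the ground-truth marker assignment) when the cohort is synthetic.
    """

    samples: list[Chromatogram]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("cohort must contain at least one sample")
        lengths = {len(s.resistance) for s in self.samples}
        if len(lengths) != 1:
            raise ValueError(f"mixed grid lengths in cohort: {sorted(lengths)}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicated sample_id {dup!r}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Chromatogram]:
        return iter(self.samples)

    @property
    def grid_length(self) -> int:
        return len(self.samples[0].resistance)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.samples])

    @property
    def y(self) -> np.ndarray:
        """Binary class indicator: control -> 0, cancer -> 1."""
        return (self.labels == CANCER).astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_indices(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group label {group!r}")
        return np.flatnonzero(self.labels == group)

    def group_size(self, group: str) -> int:
        return len(self.group_indices(group))

    def resistance_matrix(self) -> np.ndarray:
        """Raw traces stacked as an (n_samples, grid_length) array."""
        return np.stack([s.resistance for s in self.samples])

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort([self.samples[i] for i in indices],
                      metadata=dict(self.metadata))
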