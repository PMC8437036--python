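"""Time-stamped concentration series with validity flags.

The central in-memory record for one chemical species in one well/tube:
strictly increasing times (hours), concentrations (uM), and a boolean
validity mask used to exclude artifact-affected or below-detection points
from fits without dropping them from the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .conditions import ConditionSpec


@dataclass
class ConcentrationSeries:
    times: np.ndarray  # h, strictly increasing
    values: np.ndarray  # uM
    species: str = "PCA_red"
    condition: Optional[ConditionSpec] = None
    replicate: Optional[int] = None
    valid: Optional[np.ndarray] = None  # bool mask; None means all valid

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.times.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.size != self.times.size:
                raise ValueError("valid mask must match series length")
        # Negative concentrations are physically impossible; they must be
        # clipped and flagged upstream (see calibrate_fluorescence).
        if np.any(self.values[self.valid] < 0):
            raise ValueError("valid points must have non-negative values")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def with_flags(self, invalid_where: np.ndarray) -> "ConcentrationSeries":
        """Return a copy with additional points flagged invalid."""
        return replace(self, valid=self.valid & ~np.asarray(invalid_where, bool))

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) restricted to valid points."""
        return self.times[self.valid], self.values[self.valid]


def mean_of_replicates(series_list: list[ConcentrationSeries]) -> ConcentrationSeries:
    """Pointwise mean across replicate series sharing one time grid.

    A time point is valid in the mean only where it is valid in every
    replicate, so artifact exclusions propagate.  Grids must match exactly.
    """
    if not series_list:
        raise ValueError("need at least one replicate")
    first = series_list[0]
    for s in series_list[1:]:
        if not np.array_equal(s.times, first.times):
            raise ValueError("replicates must share an identical time grid")
        if s.species != first.species:
            raise ValueError("replicates must describe the same species")
    values = np.mean([s.values for s in series_list], axis=0)
    valid = np.logical_and.reduce([s.valid for s in series_list])
    # Means of partially-invalid points may be negative; keep them flagged.
    values = np.where(valid, values, np.maximum(values, 0.0))
    return ConcentrationSeries(
        times=first.times.copy(),
        values=values,
        species=first.species,
        condition=first.condition,
        replicate=None,
        valid=valid,
    )


__all__ = ["ConcentrationSeries", "mean_of_replicates"]
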