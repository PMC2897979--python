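"""Experimental design of a rifampicin chase time course."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sampling grid of the chase experiment, minutes after rifampicin addition.
DEFAULT_TIMEPOINTS = (0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 60.0)


@dataclass(frozen=True)
class ChaseDesign:
    """Sampling design of a transcription-arrest (rifampicin) chase.

    Parameters
    ----------
    timepoints : sequence of float
        Harvest times in minutes; strictly increasing, first must be 0
        (the pre-treatment reference sample).
    replicates : int
        Number of biological replicate cultures (>= 1).
    noise_sigma : float
        Standard deviation of multiplicative measurement noise on the
        natural-log scale (intensity data have roughly constant
        coefficient of variation).
    saturation_cap : float
        Maximum reportable signal; intensities are hard-clipped here,
        emulating scanner/hybridization saturation of highly expressed
        transcripts.
    seed : int
        Base seed for all randomness derived from this design.
    """

    timepoints: tuple = field(default=DEFAULT_TIMEPOINTS)
    replicates: int = 3
    noise_sigma: float = 0.1
    saturation_cap: float = float("inf")
    seed: int = 0

    def __post_init__(self):
        t = tuple(float(x) for x in self.timepoints)
        object.__setattr__(self, "timepoints", t)
        if len(t) < 2:
            raise ValueError("need at least two timepoints")
        if t[0] != 0.0:
            raise ValueError("first timepoint must be 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.saturation_cap > 0:
            raise ValueError("saturation_cap must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.timepoints, dtype=float)

    @property
    def horizon(self) -> float:
        """Last sampled minute of the chase."""
        return self.timepoints[-1]

    def time_columns(self) -> list:
        """Column labels used in the on-disk tables (``t0``, ``t2.5``, ...)."""
        return [format_time_column(t) for t in self.timepoints]


def format_time_column(t: float) -> str:
    return "t%g" % t


def parse_time_column(name: str) -> float:
    if not name.startswith("t"):
        raise ValueError(f"not a time column: {name!r}")
    return float(name[1:])
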