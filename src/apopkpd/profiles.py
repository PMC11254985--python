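"""Time-profile container shared by the PK and PD layers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class InvalidProfileError(ValueError):
    """Raised when a time grid or profile violates its invariants."""


def default_grid(t_end_min: float = 90.0, step_min: float = 0.25) -> np.ndarray:
    """Uniform time grid in minutes from 0 to ``t_end_min`` inclusive.

    The 0.25-min default keeps grid-based peak and threshold-crossing times
    accurate to well under half a minute.
    """
    n = int(round(t_end_min / step_min))
    return np.linspace(0.0, t_end_min, n + 1)


def validate_grid(times_min: np.ndarray) -> np.ndarray:
    times = np.asarray(times_min, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise InvalidProfileError("time grid must be a 1-D vector of at least 2 points")
    if times[0] != 0.0:
        raise InvalidProfileError("time grid must start at 0")
    if not np.all(np.diff(times) > 0):
        raise InvalidProfileError("time grid must be strictly increasing")
    return times


@dataclass(frozen=True)
class TimeProfile:
    """A paired time grid (minutes, starting at 0) and values.

    Values are ng/mL for concentration profiles and UPDRS points for
    effect-change profiles (change profiles are <= 0 by construction).
    """

    times_min: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = validate_grid(self.times_min)
        values = np.asarray(self.values, dtype=float)
        if values.shape != times.shape:
            raise InvalidProfileError("times and values must have the same length")
        if not np.all(np.isfinite(values)):
            raise InvalidProfileError("profile values must be finite")
        object.__setattr__(self, "times_min", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times_min.size

    def to_frame(self, value_name: str = "value") -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times_min, value_name: self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
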