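"""Piecewise-linear subject trajectories on the TTC scale.

A subject's underlying TTC course is modelled as a line in time plus a
step function driven by dose changes:

    m(t) = intercept + slope * t + offset(t)

where ``offset`` is piecewise constant (e.g. the dose-level coefficient of
the currently active dose).  Dose changes induce jumps; the trajectory is
evaluated left-continuously at change points (the pre-change level applies
at the instant of change).  The running average (1/t) * int_0^t m(s) ds has
a closed form per segment, used by the average-exposure association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """m(t) = intercept + slope * t + step offset(t), offsets switching at seg_times.

    ``seg_times`` must start at 0 and be strictly increasing; ``seg_offsets[j]``
    applies on the interval (seg_times[j], seg_times[j+1]] (and at t = 0 for
    the first segment).
    """

    intercept: float
    slope: float
    seg_times: np.ndarray = field(default_factory=lambda: np.zeros(1))
    seg_offsets: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        self.seg_times = np.atleast_1d(np.asarray(self.seg_times, dtype=float))
        self.seg_offsets = np.atleast_1d(np.asarray(self.seg_offsets, dtype=float))
        if self.seg_times[0] != 0.0:
            raise ValueError("seg_times must start at 0")
        if len(self.seg_times) != len(self.seg_offsets):
            raise ValueError("seg_times and seg_offsets must have equal length")
        if np.any(np.diff(self.seg_times) <= 0):
            raise ValueError("seg_times must be strictly increasing")
        # cumulative integral of offset(s) up to each segment start
        seg_len = np.diff(self.seg_times)
        self._cum_offset_int = np.concatenate(
            ([0.0], np.cumsum(self.seg_offsets[:-1] * seg_len))
        )

    def _segment_index(self, t: np.ndarray) -> np.ndarray:
        # left-continuous: at an exact change point the previous segment applies
        idx = np.searchsorted(self.seg_times, t, side="left") - 1
        return np.clip(idx, 0, len(self.seg_times) - 1)

    def offset(self, t):
        t_arr = np.asarray(t, dtype=float)
        out = self.seg_offsets[self._segment_index(t_arr)]
        return out if out.ndim else float(out)

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        out = self.intercept + self.slope * t_arr + self.seg_offsets[self._segment_index(t_arr)]
        return out if out.ndim else float(out)

    def integral(self, t):
        """int_0^t m(s) ds in closed form."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be >= 0")
        idx = self._segment_index(t_arr)
        off_int = self._cum_offset_int[idx] + self.seg_offsets[idx] * (t_arr - self.seg_times[idx])
        out = self.intercept * t_arr + 0.5 * self.slope * t_arr**2 + off_int
        return out if out.ndim else float(out)

    def average(self, t):
        """(1/t) int_0^t m(s) ds; defined as m(0) at t = 0 (continuity limit)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be >= 0")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(t_arr > 0, self.integral(np.maximum(t_arr, 1e-300)) / np.where(t_arr > 0, t_arr, 1.0),
                           self.intercept + self.seg_offsets[0])
        return out if out.ndim else float(out)

    def change_points(self) -> np.ndarray:
        """Interior offset-change times (excludes the origin)."""
        return self.seg_times[1:]
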