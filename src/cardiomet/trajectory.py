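"""Piecewise trajectories used as ground-truth inputs to the simulators.

A :class:`Trajectory` is a deterministic function of time defined by
breakpoints and values, with either step (piecewise-constant) or linear
interpolation.  It is used for heart-rate programmes (bpm), metabolic-rate
programmes (kJ h^-1) and ambient-temperature programmes (deg C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "RateTrajectory"]


@dataclass(frozen=True)
class Trajectory:
    """Piecewise function of time (seconds from start).

    Parameters
    ----------
    breakpoints
        Strictly increasing times in seconds, starting at 0.  The last
        breakpoint is the total duration.
    values
        For ``interpolation="step"``: one value per segment, i.e.
        ``len(breakpoints) - 1`` entries.  For ``"linear"``: one value per
        breakpoint (node values).
    """

    breakpoints: tuple = ()
    values: tuple = ()
    interpolation: str = "step"

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if bp.size < 2:
            raise ValueError("need at least two breakpoints (start and end)")
        if not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if bp[0] != 0:
            raise ValueError("breakpoints must start at 0")
        if self.interpolation == "step":
            if vals.size != bp.size - 1:
                raise ValueError("step trajectory needs one value per segment")
        elif self.interpolation == "linear":
            if vals.size != bp.size:
                raise ValueError("linear trajectory needs one value per breakpoint")
        else:
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        object.__setattr__(self, "breakpoints", tuple(bp))
        object.__setattr__(self, "values", tuple(vals))

    @property
    def duration(self) -> float:
        return self.breakpoints[-1]

    @classmethod
    def constant(cls, value: float, duration: float) -> "Trajectory":
        return cls((0.0, float(duration)), (float(value),), "step")

    def __call__(self, t) -> np.ndarray:
        """Evaluate the trajectory at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        bp = np.asarray(self.breakpoints)
        vals = np.asarray(self.values)
        if self.interpolation == "linear":
            return np.interp(t, bp, vals)
        idx = np.clip(np.searchsorted(bp, t, side="right") - 1, 0, vals.size - 1)
        return vals[idx]

    def integral(self, t0: float = 0.0, t1: float | None = None) -> float:
        """Exact integral of the trajectory over ``[t0, t1]``."""
        if t1 is None:
            t1 = self.duration
        # integrate on a grid refined at breakpoints; exact for both modes
        knots = np.asarray(self.breakpoints)
        pts = np.unique(np.concatenate([[t0, t1], knots[(knots > t0) & (knots < t1)]]))
        total = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            if self.interpolation == "step":
                total += self((a + b) / 2) * (b - a)
            else:
                total += 0.5 * (self(a) + self(b)) * (b - a)
        return float(total)


@dataclass(frozen=True)
class RateTrajectory(Trajectory):
    """Heart-rate programme in beats per minute.

    Rates are bounded to the physiologically plausible 0--1200 bpm envelope
    (field observations span roughly 58--1068 bpm).
    """

    max_rate_bpm: float = field(default=1200.0, compare=False)

    def __post_init__(self):
        super().__post_init__()
        vals = np.asarray(self.values)
        if np.any(vals < 0) or np.any(vals > self.max_rate_bpm):
            raise ValueError(f"rates must lie in [0, {self.max_rate_bpm}] bpm")

    def expected_beats(self, t0: float = 0.0, t1: float | None = None) -> float:
        """Analytic expected beat count over an interval (rate integral / 60)."""
        return self.integral(t0, t1) / 60.0

    def beat_times(self, grid_dt: float = 1e-3) -> np.ndarray:
        """Deterministic beat times: crossings of the integrated rate.

        The cumulative beat count Lambda(t) = int_0^t r(s)/60 ds is computed on
        a fine grid and inverted at integer counts, so the emitted event list
        matches the analytic integral to within one beat on any interval.
        """
        t = np.arange(0.0, self.duration + grid_dt, grid_dt)
        t[-1] = min(t[-1], self.duration)
        rate = self(t) / 60.0
        cum = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2 * np.diff(t))])
        n = int(np.floor(cum[-1] + 1e-9))
        if n == 0:
            return np.empty(0)
        return np.interp(np.arange(1, n + 1), cum, t)
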