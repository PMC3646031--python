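"""Containers for recurrence-free-interval (RFI) and hazard curves.

Times are always years post-resection; the escape-clock time used by the
model formulas is ``time - tau``.  Conversion is centralised here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RFICurve:
    """A Kaplan-Meier-style recurrence-free-interval curve.

    times: years post-resection (strictly increasing);
    rfi: recurrence-free fractions in [0, 1];
    tau: normalization time (f = 1 at tau);
    se: optional pointwise standard errors;
    n_at_risk: optional numbers at risk.
    """

    times: np.ndarray
    rfi: np.ndarray
    tau: float = 0.0
    se: np.ndarray | None = None
    n_at_risk: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rfi = np.asarray(self.rfi, dtype=float)
        if self.times.shape != self.rfi.shape:
            raise ValueError("times and rfi must have the same shape")
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("curve must be a non-empty 1-d table")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.rfi < -1e-12) or np.any(self.rfi > 1 + 1e-12):
            raise ValueError("rfi values must lie in [0, 1]")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.rfi) <= 1e-12))

    def escape_clock_times(self) -> np.ndarray:
        """Times on the escape clock, t = time - tau."""
        return self.times - self.tau

    def interpolate(self, times) -> np.ndarray:
        """Linear interpolation of the curve at arbitrary times within range."""
        times = np.asarray(times, dtype=float)
        if np.any(times < self.times[0] - 1e-12) or np.any(times > self.times[-1] + 1e-12):
            raise ValueError("interpolation times outside the curve's span")
        return np.interp(times, self.times, self.rfi)


@dataclass
class HazardCurve:
    """Hazard-rate estimates on a time grid (years post-resection).

    h is in 1/year and non-negative; ``extrapolated`` flags points beyond the
    original data range; ``meta`` records smoothing/extrapolation choices.
    """

    times: np.ndarray
    h: np.ndarray
    extrapolated: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.times.shape != self.h.shape:
            raise ValueError("times and h must have the same shape")
        if np.any(self.h < -1e-12):
            raise ValueError("hazard values must be >= 0")
        if self.extrapolated is None:
            self.extrapolated = np.zeros(self.times.shape, dtype=bool)
        else:
            self.extrapolated = np.asarray(self.extrapolated, dtype=bool)

    def interpolate(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if np.any(times < self.times[0] - 1e-12) or np.any(times > self.times[-1] + 1e-12):
            raise ValueError("interpolation times outside the hazard curve's span")
        return np.interp(times, self.times, self.h)
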