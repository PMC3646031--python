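"""Reading, writing and transforming RFI curve tables.

File format: CSV with header ``time_years,rfi`` plus optional ``se`` and
``n_at_risk`` columns, times in years post-resection, full double precision.
Event tables round-trip as ``patient_id,time_years,event``.

The hazard estimator follows the life-table convention: on each bin,
h = -delta ln f / delta t, optionally smoothed with a Gaussian kernel.
Extrapolation beyond the data range defaults to holding the last value
constant (the least-assumption rule for a non-increasing tail); a log-linear
tail fitted to the last points is available as an alternative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .curves import HazardCurve, RFICurve

__all__ = [
    "read_rfi_csv",
    "write_rfi_csv",
    "read_event_table",
    "write_event_table",
    "normalize_at_tau",
    "hazard_from_km",
    "extrapolate_hazard",
]


def write_rfi_csv(curve: RFICurve, path) -> None:
    data = {"time_years": curve.times, "rfi": curve.rfi}
    if curve.se is not None:
        data["se"] = curve.se
    if curve.n_at_risk is not None:
        data["n_at_risk"] = curve.n_at_risk
    pd.DataFrame(data).to_csv(path, index=False)


def read_rfi_csv(path, tau: float = 0.0) -> RFICurve:
    """Read an RFI table; non-monotone curves are accepted but flagged."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_years", "rfi"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    bad = df.index[df[["time_years", "rfi"]].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed rows at lines {[i + 2 for i in bad]}")
    curve = RFICurve(
        times=df["time_years"].to_numpy(),
        rfi=df["rfi"].to_numpy(),
        tau=tau,
        se=df["se"].to_numpy() if "se" in df.columns else None,
        n_at_risk=df["n_at_risk"].to_numpy() if "n_at_risk" in df.columns else None,
    )
    if not curve.is_monotone:
        warnings.warn(f"{path}: RFI values are not non-increasing", stacklevel=2)
    return curve


def write_event_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("patient_id", "time_years", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return df


def normalize_at_tau(curve: RFICurve, tau: float) -> RFICurve:
    """Drop points before tau and renormalise so that f(tau) = 1.

    f(tau) is obtained by linear interpolation when tau falls between grid
    points; tau beyond the last point is rejected.
    """
    if tau > curve.times[-1] + 1e-12:
        raise ValueError(f"tau={tau} is beyond the last data point {curve.times[-1]}")
    if tau < curve.times[0] - 1e-12:
        raise ValueError(f"tau={tau} precedes the first data point {curve.times[0]}")
    f_tau = float(np.interp(tau, curve.times, curve.rfi))
    if f_tau <= 0:
        raise ValueError("f(tau) <= 0; cannot normalize")
    keep = curve.times >= tau - 1e-12
    times = curve.times[keep]
    vals = curve.rfi[keep] / f_tau
    se = curve.se[keep] / f_tau if curve.se is not None else None
    nar = curve.n_at_risk[keep] if curve.n_at_risk is not None else None
    if times.size == 0 or times[0] > tau + 1e-12:
        times = np.concatenate([[tau], times])
        vals = np.concatenate([[1.0], vals])
        se = np.concatenate([[0.0], se]) if se is not None else None
        nar = np.concatenate([[nar[0]], nar]) if nar is not None and nar.size else nar
    vals = np.clip(vals, 0.0, 1.0)
    return RFICurve(times=times, rfi=vals, tau=tau, se=se, n_at_risk=nar)


def hazard_from_km(
    curve: RFICurve,
    bin_width: float | None = None,
    smooth_bandwidth: float | None = None,
) -> HazardCurve:
    """Life-table hazard h = -delta ln f / delta t from a normalized RFI curve.

    bin_width (>= the grid spacing) resamples ln f linearly onto coarser bins
    before differencing; smooth_bandwidth applies Gaussian-kernel smoothing
    (years).  Negative finite differences are floored at zero and flagged in
    the metadata.  Hazard values are placed at bin midpoints.
    """
    if np.any(curve.rfi <= 0):
        raise ValueError("RFI values must be positive to take logarithms")
    times, logf = curve.times, np.log(curve.rfi)
    spacing = float(np.min(np.diff(times)))
    if bin_width is not None:
        if bin_width < spacing - 1e-12:
            raise ValueError(f"bin_width {bin_width} is below the grid spacing {spacing}")
        edges = np.arange(times[0], times[-1] + 1e-9, bin_width)
        if edges[-1] < times[-1] - 1e-9:
            edges = np.append(edges, times[-1])
        logf = np.interp(edges, times, logf)
        times = edges
    if len(times) < 2:
        raise ValueError("need at least two points to estimate a hazard")
    dt = np.diff(times)
    raw = -np.diff(logf) / dt
    n_negative = int(np.sum(raw < 0))
    h = np.maximum(raw, 0.0)
    mids = 0.5 * (times[:-1] + times[1:])
    meta = {
        "bin_width": bin_width if bin_width is not None else spacing,
        "n_negative_floored": n_negative,
        "smooth_bandwidth": smooth_bandwidth,
        "extrapolation": None,
    }
    if smooth_bandwidth:
        h = _gaussian_smooth(mids, h, smooth_bandwidth)
    return HazardCurve(times=mids, h=h, meta=meta)


def _gaussian_smooth(x, y, bandwidth):
    w = np.exp(-0.5 * ((x[:, None] - x[None, :]) / bandwidth) ** 2)
    return (w @ y) / w.sum(axis=1)


def extrapolate_hazard(
    hazard_curve: HazardCurve,
    t_end: float,
    rule: str = "constant",
    n_tail: int = 4,
    n_points: int = 20,
) -> HazardCurve:
    """Extend a hazard curve out to t_end (e.g. 20 years post-resection).

    rule='constant' holds the last value; rule='loglinear' fits ln h against t
    over the last n_tail points and extends the fitted exponential tail.
    Extrapolated points are flagged.  If t_end does not exceed the data range
    the input is returned unchanged.
    """
    if t_end <= hazard_curve.times[-1] + 1e-12:
        return hazard_curve
    new_t = np.linspace(hazard_curve.times[-1], t_end, n_points + 1)[1:]
    if rule == "constant":
        new_h = np.full_like(new_t, hazard_curve.h[-1])
    elif rule == "loglinear":
        tail_t = hazard_curve.times[-n_tail:]
        tail_h = hazard_curve.h[-n_tail:]
        if np.any(tail_h <= 0):
            raise ValueError("log-linear extrapolation requires positive tail hazards")
        slope, intercept = np.polyfit(tail_t, np.log(tail_h), 1)
        new_h = np.exp(intercept + slope * new_t)
    else:
        raise ValueError(f"unknown extrapolation rule {rule!r}")
    meta = dict(hazard_curve.meta, extrapolation=rule)
    return HazardCurve(
        times=np.concatenate([hazard_curve.times, new_t]),
        h=np.concatenate([hazard_curve.h, new_h]),
        extrapolated=np.concatenate(
            [hazard_curve.extrapolated, np.ones(new_t.size, dtype=bool)]
        ),
        meta=meta,
    )
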