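"""Hazard diagnostics and hidden-burden estimation.

Everything here rests on the killed-process identity for the hazard: among
patients still dormant at escape-clock time t, the hazard equals the
conditional mean of the total escape intensity I (kappa n for the Zeroth
model and Model 1, kappa_V n_V for Model 2, (a + b t) n for Model 3), and its
derivative decomposes as

    dh/dt = E_t[(L + d/dt) I]  -  Var_t[I]
          = gain_term          -  variance_term,

where L is the model generator acting on I (new seeding, s -> V transitions,
disappearance).  A rising hazard therefore requires the expected growth of
tumourigenicity among dormant patients to beat the between-patient variance
of the escape intensity -- which is why cohort hazards are so often flat or
decreasing even when tumourigenicity rises.

At t = 0 with Poisson initial counts the sign conditions reduce to
Model 1: mu p_M > lam + kappa;  Model 2: kappa_s Ns > kappa_V NV;
Model 3: b > a^2.  The Zeroth model's hazard is always non-increasing.

A relapse-rate peak (r = h f) exists iff dr/dt > 0 at t -> 0+, i.e.
dh/dt(0) > h(0)^2; the per-model peak inequalities and the Fig-style ratio
sweeps below are built on that form, with the grid search over r(t) kept as
ground truth.

Late after resection the richer models collapse onto Zeroth-type dynamics;
then the dormant-patient burden follows from the hazard curve alone:
E_t[n] = h/kappa and Var_t[n] = -h'/kappa^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .curves import HazardCurve
from .models import (
    Model1Params,
    Model2Params,
    Model3Params,
    ModelParams,
    ZerothParams,
    conditional_moments,
    escape_survival,
    hazard,
    hazard_derivative,
    make_params,
    param_names,
    relapse_rate,
)
from .simulate import conditioned_ensemble

__all__ = [
    "DecompositionResult",
    "BurdenEstimate",
    "hazard_derivative_decomposition",
    "decomposition_closed_form",
    "hazard_increasing_at",
    "hazard_increase_condition_t0",
    "relapse_peak_ratio",
    "find_relapse_rate_peak",
    "ratio_sweep",
    "burden_estimates",
    "InapplicableHazardError",
]


class InapplicableHazardError(ValueError):
    """The burden approximation requires a non-increasing hazard window."""


# ---------------------------------------------------------------------------
# escape intensity and its generator action, per model


def _intensity_and_gain(params: ModelParams, t: float, counts: dict):
    """Per-run escape intensity I and gain integrand (L + d/dt) I.

    counts holds per-type count arrays from a conditioned ensemble.
    """
    if isinstance(params, ZerothParams):
        I = params.kappa * counts["total"]
        G = np.zeros_like(I)
    elif isinstance(params, Model3Params):
        kt = params.a + params.b * t
        I = kt * counts["total"]
        G = params.b * counts["total"]
    elif isinstance(params, Model2Params):
        I = params.kappa_V * counts["V"]
        G = params.kappa_V * params.kappa_s * counts["s"]
    elif isinstance(params, Model1Params):
        n = counts["total"]
        I = params.kappa * n
        G = params.kappa * (params.mu * counts["permissive"] - params.lam * n)
    else:
        raise TypeError(f"unknown parameter type {type(params)!r}")
    return I, G


@dataclass
class DecompositionResult:
    """Monte Carlo decomposition of the hazard derivative at one time."""

    t: float
    gain_term: float
    variance_term: float
    dh_dt: float
    se_identity: float  # standard error of (gain - variance) - not of dh_dt
    n_survivors: int

    @property
    def identity_residual(self) -> float:
        return (self.gain_term - self.variance_term) - self.dh_dt

    @property
    def identity_z(self) -> float:
        return self.identity_residual / self.se_identity if self.se_identity > 0 else 0.0


def hazard_derivative_decomposition(
    params: ModelParams,
    t: float,
    n_reps: int = 20_000,
    rng_seed: int | np.random.Generator = 0,
) -> DecompositionResult:
    """Estimate gain and variance terms from a conditioned ensemble.

    dh/dt comes independently from the closed-form hazard derivative; the
    identity dh/dt = gain - variance is then checkable within Monte Carlo
    error.  The identity standard error uses the per-run influence values
    a_j = G_j - (I_j - mean(I))^2.
    """
    ens = conditioned_ensemble(params, t, n_reps, rng_seed)
    I, G = _intensity_and_gain(params, t, ens["counts"])
    m = I.size
    gain = float(G.mean())
    variance = float(I.var(ddof=1))
    infl = G - (I - I.mean()) ** 2
    se = float(infl.std(ddof=1) / math.sqrt(m))
    return DecompositionResult(
        t=float(t),
        gain_term=gain,
        variance_term=variance,
        dh_dt=float(hazard_derivative(params, t)),
        se_identity=se,
        n_survivors=m,
    )


def decomposition_closed_form(params: ModelParams, t: float) -> tuple[float, float]:
    """Analytic (gain, variance) terms from the conditioned moments."""
    mom = conditional_moments(params, t)
    if isinstance(params, ZerothParams):
        return 0.0, params.kappa**2 * mom["total"][1]
    if isinstance(params, Model3Params):
        kt = params.a + params.b * t
        return params.b * mom["total"][0], kt * kt * mom["total"][1]
    if isinstance(params, Model2Params):
        return (
            params.kappa_V * params.kappa_s * mom["s"][0],
            params.kappa_V**2 * mom["V"][1],
        )
    if isinstance(params, Model1Params):
        gain = params.kappa * (
            params.mu * mom["permissive"][0] - params.lam * mom["total"][0]
        )
        return gain, params.kappa**2 * mom["total"][1]
    raise TypeError(f"unknown parameter type {type(params)!r}")


# ---------------------------------------------------------------------------
# hazard-increase conditions


def hazard_increasing_at(params: ModelParams, t: float) -> tuple[bool, float]:
    """Whether dh/dt > 0 at escape-clock time t, with the margin dh/dt."""
    margin = float(hazard_derivative(params, t))
    return margin > 0, margin


def hazard_increase_condition_t0(params: ModelParams) -> tuple[bool, float, float]:
    """Analytic t=0 increase condition (lhs, rhs): hazard rising iff lhs > rhs.

    Model 1: mu p_M > lam + kappa; Model 2: kappa_s Ns > kappa_V NV;
    Model 3: b > a^2; Zeroth: never (lhs = 0, rhs = kappa^2 N as a margin).
    """
    if isinstance(params, Model1Params):
        lhs, rhs = params.mu * params.p_M, params.lam + params.kappa
    elif isinstance(params, Model2Params):
        lhs, rhs = params.kappa_s * params.Ns_bar, params.kappa_V * params.NV_bar
    elif isinstance(params, Model3Params):
        lhs, rhs = params.b, params.a**2
    elif isinstance(params, ZerothParams):
        lhs, rhs = 0.0, params.kappa**2 * params.N_bar
    else:
        raise TypeError(f"unknown parameter type {type(params)!r}")
    return lhs > rhs, lhs, rhs


# ---------------------------------------------------------------------------
# relapse-rate peaks and ratio sweeps


def relapse_peak_ratio(params: ModelParams) -> float:
    """rhs/lhs of the t->0+ relapse-peak inequality (peak iff ratio < 1).

    From dr/dt(0) > 0 <=> dh/dt(0) > h(0)^2 with Poisson initial counts:
    Model 1: mu p_M > lam + kappa (1 + N);
    Model 2: kappa_s Ns > kappa_V NV (1 + NV);
    Model 3: b > a^2 (1 + N).
    """
    if isinstance(params, Model1Params):
        lhs = params.mu * params.p_M
        rhs = params.lam + params.kappa * (1.0 + params.N_bar)
    elif isinstance(params, Model2Params):
        lhs = params.kappa_s * params.Ns_bar
        rhs = params.kappa_V * params.NV_bar * (1.0 + params.NV_bar)
    elif isinstance(params, Model3Params):
        lhs = params.b
        rhs = params.a**2 * (1.0 + params.N_bar)
    else:
        raise TypeError("relapse-peak ratio is defined for Models 1-3 only")
    if lhs <= 0:
        return math.inf
    return rhs / lhs


def find_relapse_rate_peak(
    params: ModelParams,
    t_max: float,
    n_grid: int = 2000,
) -> float | None:
    """Interior argmax of the relapse rate r(t) on (0, t_max], or None.

    Dense grid search refined by bounded scalar optimisation; returns None
    when the maximum sits at the t -> 0 boundary (monotone-decreasing r).
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    t = np.linspace(0.0, t_max, n_grid + 1)
    r = relapse_rate(params, t)
    i = int(np.argmax(r))
    if i == 0:
        return None
    if i == n_grid:
        # maximum at the right edge: not an interior peak within (0, t_max]
        return None
    lo, hi = t[i - 1], t[i + 1]
    res = minimize_scalar(
        lambda x: -relapse_rate(params, float(x)), bounds=(lo, hi), method="bounded"
    )
    return float(res.x)


_SWEEP_DEFAULTS = {"model1": "kappa", "model2": "NV_bar", "model3": "a"}


def ratio_sweep(
    model: str,
    base_params: dict,
    target_ratios=(2.0, 1.0, 0.2, 0.04),
    sweep_param: str | None = None,
    t_max: float = 30.0,
    times: np.ndarray | None = None,
    bracket: tuple[float, float] = (0.0, 50.0),
) -> list[dict]:
    """Tune one parameter to hit each relapse-peak ratio; return curves + flags.

    The swept parameter defaults to the one whose reduction mimics a
    dormancy-inducing therapy (kappa for Model 1, NV_bar for Model 2, a for
    Model 3).  Each entry holds the tuned params, the achieved ratio, the RFI
    curve and relapse-rate values on a grid, and the interior-peak flag from
    the grid search.  Unreachable ratios are reported, not raised.
    """
    sweep_param = sweep_param or _SWEEP_DEFAULTS[model]
    if sweep_param not in param_names(model):
        raise ValueError(f"{sweep_param!r} is not a parameter of {model}")
    if times is None:
        times = np.linspace(0.0, t_max, 301)
    out = []
    for target in target_ratios:
        entry = {"target_ratio": float(target), "sweep_param": sweep_param}
        try:
            value = _solve_ratio(model, base_params, sweep_param, float(target), bracket)
        except ValueError as err:
            entry.update({"reachable": False, "reason": str(err)})
            out.append(entry)
            continue
        params = make_params(model, {**base_params, sweep_param: value})
        peak = find_relapse_rate_peak(params, t_max)
        entry.update(
            {
                "reachable": True,
                "value": value,
                "achieved_ratio": relapse_peak_ratio(params),
                "params": {n: getattr(params, n) for n in param_names(model)},
                "times": times,
                "rfi": np.atleast_1d(escape_survival(params, times)),
                "relapse_rate": np.atleast_1d(relapse_rate(params, times)),
                "peak_time": peak,
                "has_interior_peak": peak is not None,
            }
        )
        out.append(entry)
    return out


def _solve_ratio(model, base_params, sweep_param, target, bracket):
    def f(x):
        params = make_params(model, {**base_params, sweep_param: x})
        r = relapse_peak_ratio(params)
        return (r - target) if math.isfinite(r) else math.inf

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if not (math.isfinite(flo) and math.isfinite(fhi)):
        raise ValueError(f"ratio undefined over the bracket for {sweep_param}")
    if flo * fhi > 0:
        raise ValueError(
            f"target ratio {target} unreachable by {sweep_param} in [{lo}, {hi}]"
        )
    root = brentq(f, lo, hi, xtol=1e-12, rtol=1e-10)
    return float(root)


# ---------------------------------------------------------------------------
# micrometastasis burden from a hazard curve


@dataclass
class BurdenEstimate:
    """Estimated dormant-patient micrometastasis burden at one time."""

    t: float
    mean_n: float
    var_n: float
    sd_n: float
    kappa: float


def burden_estimates(
    hazard_curve: HazardCurve,
    kappa: float,
    times,
    monotone_tol: float = 1e-9,
    dh_dt=None,
) -> list[BurdenEstimate]:
    """Late-time burden among dormant patients: mean = h/kappa, var = -h'/kappa^2.

    Valid only where the (smoothed/extrapolated) hazard is non-increasing --
    the late-time collapse of Models 1-3 onto Zeroth-type dynamics; an
    increasing hazard over the requested window raises
    InapplicableHazardError.  h' defaults to a finite-difference gradient of
    the curve; pass dh_dt (values at ``times``) when an analytic derivative
    is available.  Slightly negative variance estimates from numerical
    differentiation are floored at zero with a warning.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lo, hi = times.min(), times.max()
    # include the grid points bracketing the window so short windows that fall
    # between grid points are still checked
    i0 = max(int(np.searchsorted(hazard_curve.times, lo, side="right")) - 1, 0)
    i1 = min(
        int(np.searchsorted(hazard_curve.times, hi, side="left")) + 1,
        hazard_curve.times.size - 1,
    )
    window = hazard_curve.h[i0 : i1 + 1]
    if window.size >= 2 and np.any(np.diff(window) > monotone_tol * max(window.max(), 1.0)):
        raise InapplicableHazardError(
            "hazard is increasing over the requested window; the Zeroth-collapse "
            "burden approximation applies only where the hazard is non-increasing"
        )
    h = hazard_curve.interpolate(times)
    if dh_dt is not None:
        dh = np.broadcast_to(np.asarray(dh_dt, dtype=float), times.shape).copy()
    else:
        dh = np.interp(
            times, hazard_curve.times, np.gradient(hazard_curve.h, hazard_curve.times)
        )
    var = -dh / kappa**2
    if np.any(var < 0):
        warnings.warn("negative burden variance floored at 0", stacklevel=2)
        var = np.maximum(var, 0.0)
    return [
        BurdenEstimate(
            t=float(t),
            mean_n=float(hv / kappa),
            var_n=float(vv),
            sd_n=float(math.sqrt(vv)),
            kappa=kappa,
        )
        for t, hv, vv in zip(times, h, var)
    ]
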