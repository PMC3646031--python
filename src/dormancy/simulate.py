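"""Exact stochastic simulation of dormancy cohorts.

This is the ground-truth oracle for every closed form in :mod:`.models`:
patients are simulated individually from the continuous-time Markov dynamics
of each model, relapse occurring a fixed growth time tau after the first
escape event.

Models 0, 2 and 3 have independent, non-interacting lineages, so first-escape
times are sampled exactly per lineage (competing exponentials, hypoexponential
two-stage waits, and inverse-CDF sampling of the integrated rate a t + b t^2/2
respectively).  Model 1's seeding dynamics couple lineage counts, so it runs a
Gillespie loop with an explicit event cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import RFICurve
from .models import (
    Model1Params,
    Model2Params,
    Model3Params,
    ModelParams,
    ZerothParams,
)

__all__ = [
    "PatientOutcome",
    "CensoringSpec",
    "EventCapExceeded",
    "ConditioningError",
    "simulate_patient",
    "simulate_cohort",
    "km_estimate",
    "conditioned_ensemble",
]

NEVER = math.inf
_EVENT_CAP = 1_000_000


class EventCapExceeded(RuntimeError):
    """A Model 1 patient exceeded the per-patient event cap (supercritical seeding)."""


class ConditioningError(RuntimeError):
    """Too few simulated patients survived the no-escape conditioning."""


@dataclass(frozen=True)
class PatientOutcome:
    """Fate of one simulated patient.

    relapse_time/first_escape_time are years post-resection (inf = never);
    cleared means every micrometastasis disappeared before any escaped.
    """

    relapse_time: float
    first_escape_time: float
    cleared: bool


@dataclass(frozen=True)
class CensoringSpec:
    """Censoring mechanism for a simulated cohort.

    kind: 'none' | 'administrative' | 'uniform_entry'.
    administrative censors everyone still at risk at t_end;
    uniform_entry draws entry ~ U(0, t_accrual) and censors at t_end - entry.
    """

    kind: str = "none"
    t_end: float | None = None
    t_accrual: float | None = None

    def __post_init__(self):
        if self.kind not in ("none", "administrative", "uniform_entry"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        if self.kind == "administrative" and not (self.t_end and self.t_end > 0):
            raise ValueError("administrative censoring requires t_end > 0")
        if self.kind == "uniform_entry" and not (
            self.t_end and self.t_end > 0 and self.t_accrual and self.t_accrual >= 0
        ):
            raise ValueError("uniform_entry censoring requires t_accrual >= 0 and t_end > 0")


# ---------------------------------------------------------------------------
# first-escape sampling (vectorised for models 0, 2, 3)


def _first_escape_zeroth(params: ZerothParams, n: int, rng) -> np.ndarray:
    N = rng.poisson(params.N_bar, size=n)
    esc = np.full(n, NEVER)
    pos = N > 0
    if params.kappa > 0:
        esc[pos] = rng.exponential(1.0, size=int(pos.sum())) / (params.kappa * N[pos])
    return esc


def _first_escape_model3(params: Model3Params, n: int, rng) -> np.ndarray:
    # min over N lineages of escape times with cumulative hazard a t + b t^2/2
    # equals the inverse integrated rate at E/N, E ~ Exp(1).
    N = rng.poisson(params.N_bar, size=n)
    esc = np.full(n, NEVER)
    pos = N > 0
    a, b = params.a, params.b
    if (a > 0 or b > 0) and pos.any():
        E = rng.exponential(1.0, size=int(pos.sum())) / N[pos]
        if b > 0:
            esc[pos] = (-a + np.sqrt(a * a + 2.0 * b * E)) / b
        else:
            esc[pos] = E / a
    return esc


def _first_escape_model2(params: Model2Params, n: int, rng) -> np.ndarray:
    Ns = rng.poisson(params.Ns_bar, size=n)
    NV = rng.poisson(params.NV_bar, size=n)
    esc = np.full(n, NEVER)
    if params.kappa_V > 0:
        pos = NV > 0
        esc[pos] = rng.exponential(1.0, size=int(pos.sum())) / (params.kappa_V * NV[pos])
        if params.kappa_s > 0:
            total = int(Ns.sum())
            if total:
                waits = rng.exponential(1.0 / params.kappa_s, size=total) + rng.exponential(
                    1.0 / params.kappa_V, size=total
                )
                owner = np.repeat(np.arange(n), Ns)
                np.minimum.at(esc, owner, waits)
    return esc


def _gillespie_model1(params: Model1Params, rng, t_stop: float = math.inf):
    """Run one Model 1 patient to first escape, clearance, or t_stop.

    Returns (first_escape_time, cleared, n_perm, n_non) where the counts are
    the state at the stopping time (useful for conditioned ensembles).
    """
    n0 = rng.poisson(params.N_bar)
    n_perm = rng.binomial(n0, params.p_M) if n0 else 0
    n_non = n0 - n_perm
    k, lam, mu = params.kappa, params.lam, params.mu
    t = 0.0
    for _ in range(_EVENT_CAP):
        n = n_perm + n_non
        if n == 0:
            return NEVER, True, 0, 0
        r_escape = k * n
        r_death = lam * n
        r_seed = mu * n_perm
        total = r_escape + r_death + r_seed
        if total == 0:
            return NEVER, False, n_perm, n_non
        t += rng.exponential(1.0 / total)
        if t >= t_stop:
            return NEVER, False, n_perm, n_non
        u = rng.random() * total
        if u < r_escape:
            return t, False, n_perm, n_non
        if u < r_escape + r_death:
            if rng.random() * n < n_perm:
                n_perm -= 1
            else:
                n_non -= 1
        else:
            n_perm += 1
    raise EventCapExceeded(
        f"Model 1 patient exceeded {_EVENT_CAP} events (mu*p_M likely supercritical)"
    )


def simulate_patient(params: ModelParams, tau: float, rng_seed) -> PatientOutcome:
    """Simulate one patient; relapse occurs at first escape + tau.

    rng_seed may be an int or a numpy Generator.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    if isinstance(params, Model1Params):
        esc, cleared, _, _ = _gillespie_model1(params, rng)
    else:
        esc = float(_first_escape_dispatch(params, 1, rng)[0])
        # models 0/2/3 have no disappearance: a never-escaping patient whose
        # lineages all escape almost surely must have started with none
        cleared = math.isinf(esc) and _started_empty(params)
    relapse = esc + tau if math.isfinite(esc) else NEVER
    return PatientOutcome(relapse_time=relapse, first_escape_time=esc, cleared=cleared)


def _started_empty(params) -> bool:
    if isinstance(params, ZerothParams):
        return params.kappa > 0
    if isinstance(params, Model3Params):
        return params.a > 0 or params.b > 0
    if isinstance(params, Model2Params):
        return params.kappa_V > 0 and (params.kappa_s > 0 or params.Ns_bar == 0)
    return False


def _first_escape_dispatch(params, n, rng):
    if isinstance(params, ZerothParams):
        return _first_escape_zeroth(params, n, rng)
    if isinstance(params, Model2Params):
        return _first_escape_model2(params, n, rng)
    if isinstance(params, Model3Params):
        return _first_escape_model3(params, n, rng)
    raise TypeError(f"unknown parameter type {type(params)!r}")


def first_escape_times(
    params: ModelParams,
    n_patients: int,
    rng,
    kappa_heterogeneity=None,
) -> np.ndarray:
    """Vector of first-escape times (years, inf = never) for a cohort.

    kappa_heterogeneity (Zeroth only): ('two_point', (k1, k2, w1)) or
    ('gamma', (shape, mean)) draws a per-patient escape rate; used to study
    how between-patient variability flattens cohort hazards.
    """
    if isinstance(params, Model1Params):
        out = np.empty(n_patients)
        for i in range(n_patients):
            out[i], _, _, _ = _gillespie_model1(params, rng)
        return out
    if kappa_heterogeneity is not None:
        if not isinstance(params, ZerothParams):
            raise ValueError("kappa heterogeneity is only supported for the Zeroth model")
        kind, args = kappa_heterogeneity
        if kind == "two_point":
            k1, k2, w1 = args
            kappas = np.where(rng.random(n_patients) < w1, k1, k2)
        elif kind == "gamma":
            shape, mean = args
            kappas = rng.gamma(shape, mean / shape, size=n_patients)
        else:
            raise ValueError(f"unknown heterogeneity kind {kind!r}")
        N = rng.poisson(params.N_bar, size=n_patients)
        esc = np.full(n_patients, NEVER)
        pos = (N > 0) & (kappas > 0)
        esc[pos] = rng.exponential(1.0, size=int(pos.sum())) / (kappas[pos] * N[pos])
        return esc
    return _first_escape_dispatch(params, n_patients, rng)


# ---------------------------------------------------------------------------
# cohorts, event tables, Kaplan-Meier


def simulate_cohort(
    n_patients: int,
    params: ModelParams,
    tau: float,
    censoring: CensoringSpec | None = None,
    rng_seed: int | np.random.Generator = 0,
    kappa_heterogeneity=None,
) -> pd.DataFrame:
    """Simulate a cohort and return an event table.

    Columns: patient_id, time_years, event ('relapse' | 'censored').
    Deterministic given the seed.  Patients who never relapse are censored at
    the administrative horizon, or carry time inf under censoring='none'
    (handled downstream by km_estimate).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    censoring = censoring or CensoringSpec()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    esc = first_escape_times(params, n_patients, rng, kappa_heterogeneity)
    relapse = esc + tau
    if censoring.kind == "none":
        cens_time = np.full(n_patients, NEVER)
    elif censoring.kind == "administrative":
        cens_time = np.full(n_patients, float(censoring.t_end))
    else:
        entry = rng.uniform(0.0, censoring.t_accrual, size=n_patients)
        cens_time = np.maximum(censoring.t_end - entry, 0.0)
    relapsed = np.isfinite(relapse) & (relapse <= cens_time)
    obs = np.where(relapsed, relapse, cens_time)
    return pd.DataFrame(
        {
            "patient_id": np.arange(n_patients),
            "time_years": obs,
            "event": np.where(relapsed, "relapse", "censored"),
        }
    )


def km_estimate(event_table: pd.DataFrame, tau: float = 0.0) -> RFICurve:
    """Kaplan-Meier product-limit RFI curve with Greenwood standard errors.

    Uses lifelines' KaplanMeierFitter; the curve is evaluated at the observed
    event times.  Infinite censoring times (censoring='none') keep patients at
    risk beyond the last event, implemented by clipping them just past it.
    """
    if event_table is None or len(event_table) == 0:
        raise ValueError("event table is empty")
    from lifelines import KaplanMeierFitter

    times = event_table["time_years"].to_numpy(dtype=float)
    observed = (event_table["event"].to_numpy() == "relapse").astype(int)
    finite = times[np.isfinite(times)]
    horizon = (finite.max() if finite.size else 0.0) + 1.0
    times = np.where(np.isfinite(times), times, horizon)

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=observed)
    event_times = np.asarray(sorted(set(times[observed == 1])), dtype=float)
    if event_times.size == 0:
        # all censored: S == 1 at the censoring times
        grid = np.unique(times)
        return RFICurve(times=grid, rfi=np.ones_like(grid), tau=tau, se=np.zeros_like(grid))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    anchor = tau < event_times[0] and not np.any(times < tau)

    # Greenwood variance from the fitted event table
    et = kmf.event_table
    d = et["observed"].to_numpy(dtype=float)
    n_at_risk = et["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0)
    cum = np.cumsum(terms)
    cum_at = np.interp(event_times, et.index.to_numpy(dtype=float), cum)
    se = surv * np.sqrt(cum_at)
    n_at = np.interp(event_times, et.index.to_numpy(dtype=float), n_at_risk)
    if anchor:
        # no observation precedes tau, so S(tau) = 1 exactly: anchor the curve
        event_times = np.concatenate([[tau], event_times])
        surv = np.concatenate([[1.0], surv])
        se = np.concatenate([[0.0], se])
        n_at = np.concatenate([[float(len(times))], n_at])
    return RFICurve(times=event_times, rfi=surv, tau=tau, se=se, n_at_risk=n_at)


# ---------------------------------------------------------------------------
# conditioned (no-escape-by-t) ensembles


def conditioned_ensemble(
    params: ModelParams,
    t: float,
    n_reps: int,
    rng_seed: int | np.random.Generator = 0,
    min_survivors: int = 100,
) -> dict:
    """Empirical micrometastasis-count moments among runs with no escape by t.

    Returns {'n_survivors', 'counts': {type: array}, 'moments': {type: (mean,
    var, se_mean)}} with a 'total' type.  Raises ConditioningError if fewer
    than min_survivors runs survive the conditioning.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    counts: dict[str, np.ndarray]
    if isinstance(params, ZerothParams):
        p_dormant = math.exp(-params.kappa * t)
        N = rng.poisson(params.N_bar, size=n_reps)
        escaped = rng.binomial(N, 1.0 - p_dormant)
        keep = escaped == 0
        counts = {"total": N[keep].astype(float)}
    elif isinstance(params, Model3Params):
        p_dormant = math.exp(-(params.a * t + 0.5 * params.b * t * t))
        N = rng.poisson(params.N_bar, size=n_reps)
        escaped = rng.binomial(N, 1.0 - p_dormant)
        keep = escaped == 0
        counts = {"total": N[keep].astype(float)}
    elif isinstance(params, Model2Params):
        ks, kV = params.kappa_s, params.kappa_V
        Ns = rng.poisson(params.Ns_bar, size=n_reps)
        NV = rng.poisson(params.NV_bar, size=n_reps)
        pV_escape = 1.0 - math.exp(-kV * t)
        escV = rng.binomial(NV, pV_escape)
        p_still_s = math.exp(-ks * t)
        from .models import _prob_in_V  # exact trinomial cell probabilities

        p_in_V = float(_prob_in_V(ks, kV, t))
        p_escaped_s = max(1.0 - p_still_s - p_in_V, 0.0)
        esc_s = rng.binomial(Ns, p_escaped_s)
        rem = Ns - esc_s
        denom = max(1.0 - p_escaped_s, 1e-300)
        still_s = rng.binomial(rem, p_still_s / denom)
        moved = rem - still_s
        keep = (escV == 0) & (esc_s == 0)
        counts = {
            "s": still_s[keep].astype(float),
            "V": (NV[keep] + moved[keep]).astype(float),
        }
        counts["total"] = counts["s"] + counts["V"]
    elif isinstance(params, Model1Params):
        perm = np.empty(n_reps)
        non = np.empty(n_reps)
        keep = np.zeros(n_reps, dtype=bool)
        for i in range(n_reps):
            esc, _, n_p, n_n = _gillespie_model1(params, rng, t_stop=t)
            if not math.isfinite(esc):
                keep[i] = True
                perm[i], non[i] = n_p, n_n
        counts = {
            "permissive": perm[keep],
            "nonpermissive": non[keep],
            "total": perm[keep] + non[keep],
        }
    else:
        raise TypeError(f"unknown parameter type {type(params)!r}")

    n_surv = int(next(iter(counts.values())).size)
    if n_surv < min_survivors:
        raise ConditioningError(
            f"only {n_surv} of {n_reps} runs survived conditioning at t={t}; "
            f"need >= {min_survivors}"
        )
    moments = {}
    for name, arr in counts.items():
        mean = float(arr.mean())
        var = float(arr.var(ddof=1))
        moments[name] = (mean, var, math.sqrt(var / n_surv))
    return {"n_survivors": n_surv, "counts": counts, "moments": moments}
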