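"""Closed-form theory for the four dormancy models.

A patient leaves surgery with a hidden, Poisson-distributed number of
growth-restricted micrometastases.  Each micrometastasis may undergo a random
growth event ("escape") after which the patient relapses a fixed growth time
tau later.  The four models differ in what else can happen during dormancy:

* Zeroth model  -- nothing: each micrometastasis escapes at constant rate
  kappa.  Parameters {N_bar, kappa}.
* Model 1       -- micrometastases can disappear (rate lam) and, if they sit
  in a seeding-permissive micro-environment (probability p_M), can seed new
  secondary micrometastases (rate mu).  Parameters {N_bar, kappa, lam, mu, p_M}.
* Model 2       -- two sub-populations: one-step micrometastases (state V)
  escape at rate kappa_V; two-step micrometastases (state s) must first
  transition s -> V at rate kappa_s.  Parameters {Ns_bar, NV_bar, kappa_s,
  kappa_V}.
* Model 3       -- the escape rate rises linearly in time, kappa(t) = a + b t.
  Parameters {N_bar, a, b}.

This module provides, per model, the per-patient no-escape (survival)
probability, the recurrence-free-interval (RFI) curve normalised at tau, the
hazard rate h = -d ln S/dt and its analytic derivative, the relapse rate
r = h * S, and the moments of the micrometastasis count conditioned on no
escape so far (the "killed"-process moments that drive the hazard).

All lineages are independent and initial counts are Poisson, so every
survival probability has the form exp(-N_bar * (1 - q(t))) with q(t) the
per-lineage no-escape probability; Model 1's permissive lineages follow a
birth-death-escape branching process whose q solves a Riccati equation with
closed-form solution through the roots of mu q^2 - (kappa+lam+mu) q + lam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Union

import numpy as np

__all__ = [
    "ZerothParams",
    "Model1Params",
    "Model2Params",
    "Model3Params",
    "ModelParams",
    "GrowthTime",
    "escape_survival",
    "rfi_curve",
    "hazard",
    "hazard_derivative",
    "relapse_rate",
    "conditional_moments",
    "survival_batch",
    "zeroth_survival_counts",
    "zeroth_hazard_counts",
    "param_names",
    "make_params",
]


# ---------------------------------------------------------------------------
# parameter containers


def _check_nonneg(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ZerothParams:
    """One-step escape at constant rate: {N_bar, kappa}."""

    N_bar: float
    kappa: float

    model = "zeroth"

    def __post_init__(self):
        _check_nonneg(self, ("N_bar", "kappa"))


@dataclass(frozen=True)
class Model1Params:
    """Seeding + disappearance: {N_bar, kappa, lam, mu, p_M}.

    kappa: escape rate; lam: disappearance rate; mu: secondary-seeding rate of
    permissive micrometastases; p_M: probability an initial micrometastasis is
    seeding-permissive.  Secondaries are themselves permissive.
    """

    N_bar: float
    kappa: float
    lam: float
    mu: float
    p_M: float

    model = "model1"

    def __post_init__(self):
        _check_nonneg(self, ("N_bar", "kappa", "lam", "mu", "p_M"))
        if self.p_M > 1:
            raise ValueError(f"p_M must lie in [0, 1], got {self.p_M}")


@dataclass(frozen=True)
class Model2Params:
    """Two-step escape: {Ns_bar, NV_bar, kappa_s, kappa_V}."""

    Ns_bar: float
    NV_bar: float
    kappa_s: float
    kappa_V: float

    model = "model2"

    def __post_init__(self):
        _check_nonneg(self, ("Ns_bar", "NV_bar", "kappa_s", "kappa_V"))


@dataclass(frozen=True)
class Model3Params:
    """Linearly rising escape rate kappa(t) = a + b t: {N_bar, a, b}."""

    N_bar: float
    a: float
    b: float

    model = "model3"

    def __post_init__(self):
        _check_nonneg(self, ("N_bar", "a", "b"))


ModelParams = Union[ZerothParams, Model1Params, Model2Params, Model3Params]

_PARAM_CLASSES = {
    "zeroth": ZerothParams,
    "model1": Model1Params,
    "model2": Model2Params,
    "model3": Model3Params,
}


def param_names(model: str) -> tuple[str, ...]:
    """Field names of a model's parameter set, in canonical order."""
    cls = _PARAM_CLASSES[model]
    return tuple(f.name for f in fields(cls))


def make_params(model: str, values) -> ModelParams:
    """Build a params object from a mapping or a sequence in canonical order."""
    cls = _PARAM_CLASSES[model]
    if isinstance(values, dict):
        return cls(**values)
    return cls(*values)


@dataclass(frozen=True)
class GrowthTime:
    """Fixed time from escape to clinical detectability (years)."""

    tau: float

    def __post_init__(self):
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be finite and > 0, got {self.tau}")


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and >= 0")
    return t


# ---------------------------------------------------------------------------
# per-lineage no-escape probabilities q(t)

# Switch to the equal-rate limit of the two-stage form inside this relative
# window to avoid cancellation in (kV e^{-ks t} - ks e^{-kV t}) / (kV - ks).
_EQUAL_RATE_RTOL = 1e-9


def _q_two_stage_general(ks, kV, t):
    """No-escape prob. of an s-lineage: hypoexponential tail, ks != kV."""
    return (kV * np.exp(-ks * t) - ks * np.exp(-kV * t)) / (kV - ks)


def _q_two_stage_equal(k, t):
    """Equal-rate limit ks = kV = k: Erlang(2, k) tail."""
    return (1.0 + k * t) * np.exp(-k * t)


def _q_two_stage(ks, kV, t):
    if ks == kV:
        return _q_two_stage_equal(ks, t)
    scale = max(ks, kV)
    if scale > 0 and abs(ks - kV) < _EQUAL_RATE_RTOL * scale:
        return _q_two_stage_equal(0.5 * (ks + kV), t)
    return _q_two_stage_general(ks, kV, t)


def _prob_in_V(ks, kV, t):
    """P(an s-lineage has transitioned to V and not escaped by t)."""
    if ks == 0:
        return np.zeros_like(np.asarray(t, dtype=float))
    scale = max(ks, kV)
    if abs(ks - kV) < _EQUAL_RATE_RTOL * scale:
        k = 0.5 * (ks + kV)
        return k * t * np.exp(-k * t)
    return ks * (np.exp(-kV * t) - np.exp(-ks * t)) / (ks - kV)


def _q_nonpermissive(kappa, lam, t):
    """Death/escape lineage: q0 = 1 - kappa/(kappa+lam) (1 - e^{-(kappa+lam)t})."""
    kl = kappa + lam
    if kl == 0:
        return np.ones_like(np.asarray(t, dtype=float))
    return lam / kl + (kappa / kl) * np.exp(-kl * t)


def _riccati_roots(kappa, lam, mu):
    """Roots q- <= 1 <= q+ of mu q^2 - (kappa+lam+mu) q + lam (mu, kappa > 0)."""
    R = kappa + lam + mu
    D = math.sqrt(R * R - 4.0 * mu * lam)
    qp = (R + D) / (2.0 * mu)
    qm = (R - D) / (2.0 * mu)
    return qm, qp, D


def _q_permissive(kappa, lam, mu, t):
    """No-escape probability of one permissive (birth-death-escape) lineage.

    Solves q' = mu q^2 - (kappa+lam+mu) q + lam, q(0) = 1, in closed form:
    with roots qm < 1 < qp and u0 = (1-qp)/(1-qm) <= 0,
    q(t) = (qp e^{-Dt} - qm u0) / (e^{-Dt} - u0).
    """
    t = np.asarray(t, dtype=float)
    if kappa <= 0:
        return np.ones_like(t)
    if mu == 0:
        return _q_nonpermissive(kappa, lam, t)
    qm, qp, D = _riccati_roots(kappa, lam, mu)
    u0 = (1.0 - qp) / (1.0 - qm)
    w = np.exp(-D * t)
    return (qp * w - qm * u0) / (w - u0)


def _dq_permissive(kappa, lam, mu, t):
    """-q'(t) for the permissive lineage = kappa * E[n ; no escape by t]."""
    t = np.asarray(t, dtype=float)
    if kappa <= 0:
        return np.zeros_like(t)
    if mu == 0:
        kl = kappa + lam
        return kappa * np.exp(-kl * t)
    qm, qp, _ = _riccati_roots(kappa, lam, mu)
    q = _q_permissive(kappa, lam, mu, t)
    return mu * (qp - q) * (q - qm)


# ---------------------------------------------------------------------------
# survival (no-escape) probabilities


def escape_survival(params: ModelParams, t):
    """P(no micrometastasis has escaped growth restriction by escape-clock time t).

    Poisson-mixed over initial counts; equals exp(-N_bar (1 - q(t))) per
    lineage type.  Non-increasing in t with value 1 at t = 0.
    """
    t = _check_time(t)
    if isinstance(params, ZerothParams):
        out = np.exp(-params.N_bar * (1.0 - np.exp(-params.kappa * t)))
    elif isinstance(params, Model3Params):
        lam_int = params.a * t + 0.5 * params.b * t * t
        out = np.exp(-params.N_bar * (1.0 - np.exp(-lam_int)))
    elif isinstance(params, Model2Params):
        qs = _q_two_stage(params.kappa_s, params.kappa_V, t)
        qV = np.exp(-params.kappa_V * t)
        out = np.exp(-params.NV_bar * (1.0 - qV) - params.Ns_bar * (1.0 - qs))
    elif isinstance(params, Model1Params):
        qM = _q_permissive(params.kappa, params.lam, params.mu, t)
        q0 = _q_nonpermissive(params.kappa, params.lam, t)
        out = np.exp(
            -params.N_bar * (params.p_M * (1.0 - qM) + (1.0 - params.p_M) * (1.0 - q0))
        )
    else:  # pragma: no cover
        raise TypeError(f"unknown parameter type {type(params)!r}")
    return out if out.ndim else float(out)


def hazard(params: ModelParams, t, tau: float = 0.0):
    """Relapse hazard h[t + tau] = -d ln S/dt at escape-clock time t (1/year).

    tau only shifts the clinical clock; the returned value is the hazard at
    post-resection time t + tau.
    """
    t = _check_time(t)
    if isinstance(params, ZerothParams):
        out = params.N_bar * params.kappa * np.exp(-params.kappa * t)
    elif isinstance(params, Model3Params):
        lam_int = params.a * t + 0.5 * params.b * t * t
        out = params.N_bar * (params.a + params.b * t) * np.exp(-lam_int)
    elif isinstance(params, Model2Params):
        kV = params.kappa_V
        out = params.NV_bar * kV * np.exp(-kV * t) + params.Ns_bar * kV * _prob_in_V(
            params.kappa_s, kV, t
        )
    elif isinstance(params, Model1Params):
        dqM = _dq_permissive(params.kappa, params.lam, params.mu, t)
        kl = params.kappa + params.lam
        dq0 = params.kappa * np.exp(-kl * t)
        out = params.N_bar * (params.p_M * dqM + (1.0 - params.p_M) * dq0)
    else:  # pragma: no cover
        raise TypeError(f"unknown parameter type {type(params)!r}")
    return out if np.ndim(out) else float(out)


def hazard_derivative(params: ModelParams, t):
    """Analytic dh/dt at escape-clock time t (1/year^2)."""
    t = _check_time(t)
    if isinstance(params, ZerothParams):
        k = params.kappa
        out = -params.N_bar * k * k * np.exp(-k * t)
    elif isinstance(params, Model3Params):
        a, b = params.a, params.b
        kt = a + b * t
        lam_int = a * t + 0.5 * b * t * t
        out = params.N_bar * (b - kt * kt) * np.exp(-lam_int)
    elif isinstance(params, Model2Params):
        ks, kV = params.kappa_s, params.kappa_V
        # d/dt of kV * P_in_V: kV * (ks e^{-ks t} - kV P_in_V ... ) derived
        # directly from dP_in_V/dt = ks e^{-ks t} - kV P_in_V.
        pV = _prob_in_V(ks, kV, t)
        dpV = ks * np.exp(-ks * t) - kV * pV
        out = -params.NV_bar * kV * kV * np.exp(-kV * t) + params.Ns_bar * kV * dpV
    elif isinstance(params, Model1Params):
        k, lam, mu, p = params.kappa, params.lam, params.mu, params.p_M
        kl = k + lam
        dq0_term = -k * kl * np.exp(-kl * t)
        if k == 0:
            dqM_term = np.zeros_like(np.asarray(t, dtype=float))
            dq0_term = np.zeros_like(np.asarray(t, dtype=float))
        elif mu == 0:
            dqM_term = dq0_term
        else:
            q = _q_permissive(k, lam, mu, t)
            dq = _dq_permissive(k, lam, mu, t)  # = -q'
            # -q'' = (2 mu q - R)(-q')
            dqM_term = (2.0 * mu * q - (k + lam + mu)) * dq
        out = params.N_bar * (p * dqM_term + (1.0 - p) * dq0_term)
    else:  # pragma: no cover
        raise TypeError(f"unknown parameter type {type(params)!r}")
    return out if np.ndim(out) else float(out)


def relapse_rate(params: ModelParams, t, tau: float = 0.0):
    """Relapse-time density r[t + tau] = h * S (1/year).

    Integrates over t in [0, inf) to the total relapse probability (<= 1).
    """
    return hazard(params, t) * escape_survival(params, t)


def rfi_curve(params: ModelParams, tau: float, times):
    """Model RFI curve f_tau[t] at post-resection times (all >= tau).

    f_tau[t + tau] = escape_survival(t); f_tau[tau] = 1.
    Returns a curves.RFICurve.
    """
    from .curves import RFICurve

    GrowthTime(tau)  # validates tau > 0
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < tau - 1e-12):
        raise ValueError("all times must be >= tau (post-resection clock)")
    vals = np.atleast_1d(escape_survival(params, np.maximum(times - tau, 0.0)))
    return RFICurve(times=times, rfi=vals, tau=tau)


# ---------------------------------------------------------------------------
# conditioned (killed-process) moments


def conditional_moments(params: ModelParams, t) -> dict:
    """Mean/variance of micrometastasis counts among patients with no escape by t.

    Returns ``{type_name: (mean, variance)}`` plus a ``"total"`` entry.
    Lineage independence plus Poisson initial counts make every conditioned
    per-type count Poisson except Model 1's permissive type, whose lineage is
    a branching process; there the moments come from the generating-function
    solution (closed form).

    The means satisfy the hazard identity:
    zeroth/model1: h = kappa E_t[n]; model2: h = kappa_V E_t[n_V];
    model3: h = (a + b t) E_t[n].
    """
    t = float(t)
    if t < 0:
        raise ValueError("t must be >= 0")
    if isinstance(params, ZerothParams):
        m = params.N_bar * math.exp(-params.kappa * t)
        return {"total": (m, m)}
    if isinstance(params, Model3Params):
        m = params.N_bar * math.exp(-(params.a * t + 0.5 * params.b * t * t))
        return {"total": (m, m)}
    if isinstance(params, Model2Params):
        ms = params.Ns_bar * math.exp(-params.kappa_s * t)
        mV = params.NV_bar * math.exp(-params.kappa_V * t) + params.Ns_bar * float(
            _prob_in_V(params.kappa_s, params.kappa_V, t)
        )
        return {"s": (ms, ms), "V": (mV, mV), "total": (ms + mV, ms + mV)}
    if isinstance(params, Model1Params):
        k, lam, mu, p = params.kappa, params.lam, params.mu, params.p_M
        kl = k + lam
        m0 = params.N_bar * (1.0 - p) * math.exp(-kl * t)
        mM, vM = _model1_permissive_moments(params, t)
        return {
            "permissive": (mM, vM),
            "nonpermissive": (m0, m0),
            "total": (mM + m0, vM + m0),
        }
    raise TypeError(f"unknown parameter type {type(params)!r}")


def _model1_permissive_moments(params: Model1Params, t: float):
    """Conditional mean/variance of the permissive count, Poisson ancestors.

    Per ancestor lineage, with F(x,t) = E[x^n ; no escape by t]:
    m = F_x(1,t) = -q'/kappa and the second factorial moment
    v = F_xx(1,t) = 2 mu m (1-q)/kappa (from (v/m)' = 2 mu m).  For a
    Poisson(N_bar p_M) number of ancestors conditioned on no escape anywhere,
    mean = N_bar p_M m and variance = N_bar p_M (v + m).
    """
    k, lam, mu, p = params.kappa, params.lam, params.mu, params.p_M
    A = params.N_bar * p
    if A == 0:
        return 0.0, 0.0
    if k == 0:
        # no escape ever: plain branching moments, still compound-Poisson
        m = math.exp((mu - lam) * t)
        if mu == lam:
            integral_m = t
        else:
            integral_m = (math.exp((mu - lam) * t) - 1.0) / (mu - lam)
        v = 2.0 * mu * m * integral_m
        return A * m, A * (v + m)
    q = float(_q_permissive(k, lam, mu, t))
    m = float(_dq_permissive(k, lam, mu, t)) / k
    v = 2.0 * mu * m * (1.0 - q) / k
    return A * m, A * (v + m)


# ---------------------------------------------------------------------------
# general initial-count distributions for the Zeroth model

# A count distribution is given as ("poisson", mean), ("fixed", n), or
# ("mixture", [(n1, w1), (n2, w2), ...]) with weights summing to 1.


def _pgf_and_logderiv(dist, x):
    """G(x) and d ln G/dx for a count distribution, vectorised over x."""
    kind = dist[0]
    x = np.asarray(x, dtype=float)
    if kind == "poisson":
        mean = dist[1]
        return np.exp(mean * (x - 1.0)), np.full_like(x, mean)
    if kind == "fixed":
        n = dist[1]
        g = x**n
        dlog = np.where(x > 0, n / np.where(x > 0, x, 1.0), np.inf if n > 0 else 0.0)
        return g, dlog
    if kind == "mixture":
        pairs = dist[1]
        g = sum(w * x**n for n, w in pairs)
        dg = sum(w * n * x ** max(n - 1, 0) for n, w in pairs)
        return g, dg / g
    raise ValueError(f"unknown count distribution {dist!r}")


def zeroth_survival_counts(dist, kappa: float, t):
    """Zeroth-model survival E[q^N] for an arbitrary initial count distribution."""
    t = _check_time(t)
    q = np.exp(-kappa * t)
    g, _ = _pgf_and_logderiv(dist, q)
    return g if np.ndim(g) else float(g)


def zeroth_hazard_counts(dist, kappa: float, t):
    """Zeroth-model hazard for an arbitrary initial count distribution.

    h = kappa q G'(q)/G(q) with q = e^{-kappa t}; non-increasing in t for any
    initial count distribution (the Zeroth model cannot produce a rising
    hazard).
    """
    t = _check_time(t)
    q = np.exp(-kappa * t)
    _, dlog = _pgf_and_logderiv(dist, q)
    out = kappa * q * dlog
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# batched survival evaluation (used by the Monte Carlo fitter)


def survival_batch(model: str, P: np.ndarray, t: np.ndarray) -> np.ndarray:
    """escape_survival for many parameter draws at once.

    P has shape (n_draws, n_params) with columns in ``param_names(model)``
    order; t has shape (n_times,).  Returns shape (n_draws, n_times).
    """
    P = np.asarray(P, dtype=float)
    t = np.asarray(t, dtype=float)[None, :]
    if model == "zeroth":
        N, k = P[:, 0:1], P[:, 1:2]
        return np.exp(-N * (1.0 - np.exp(-k * t)))
    if model == "model3":
        N, a, b = P[:, 0:1], P[:, 1:2], P[:, 2:3]
        return np.exp(-N * (1.0 - np.exp(-(a * t + 0.5 * b * t * t))))
    if model == "model2":
        Ns, NV, ks, kV = (P[:, i : i + 1] for i in range(4))
        qV = np.exp(-kV * t)
        scale = np.maximum(ks, kV)
        near = np.abs(ks - kV) < np.maximum(1e-9 * scale, 1e-300)
        kbar = 0.5 * (ks + kV)
        diff = np.where(near, 1.0, kV - ks)
        qs_gen = (kV * np.exp(-ks * t) - ks * np.exp(-kV * t)) / diff
        qs_eq = (1.0 + kbar * t) * np.exp(-kbar * t)
        qs = np.where(near, qs_eq, qs_gen)
        return np.exp(-NV * (1.0 - qV) - Ns * (1.0 - qs))
    if model == "model1":
        N, k, lam, mu, p = (P[:, i : i + 1] for i in range(5))
        kl = k + lam
        safe_kl = np.where(kl > 0, kl, 1.0)
        q0 = np.where(kl > 0, lam / safe_kl + (k / safe_kl) * np.exp(-kl * t), 1.0)
        R = k + lam + mu
        D = np.sqrt(np.maximum(R * R - 4.0 * mu * lam, 0.0))
        safe_mu = np.where(mu > 0, mu, 1.0)
        qp = (R + D) / (2.0 * safe_mu)
        qm = (R - D) / (2.0 * safe_mu)
        one_m_qm = 1.0 - qm
        u0 = (1.0 - qp) / np.where(np.abs(one_m_qm) > 0, one_m_qm, 1.0)
        w = np.exp(-D * t)
        denom = w - u0
        q_gen = (qp * w - qm * u0) / np.where(np.abs(denom) > 0, denom, 1.0)
        qM = np.where(k <= 1e-14, 1.0, np.where(mu <= 0, q0, q_gen))
        q0 = np.where(k <= 1e-14, 1.0, q0)
        return np.exp(-N * (p * (1.0 - qM) + (1.0 - p) * (1.0 - q0)))
    raise ValueError(f"unknown model id {model!r}")
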