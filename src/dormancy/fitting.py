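"""Monte Carlo random-search fitting of dormancy models to RFI data.

The objective is the total squared deviation (tsd) between the model RFI
curve and the data at the data's time points; fitted parameters are the best
of n_samples uniform draws from per-parameter boxes.  Random search (no local
refinement) is the method of record; an optional Nelder-Mead polish is
available but off by default.

The draw stream is sequential in the sample index, so the best tsd is
non-increasing in n_samples for a common seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .curves import RFICurve
from .models import param_names, survival_batch, make_params

__all__ = ["FitConfig", "FitResult", "default_bounds", "objective", "fit_monte_carlo", "compare_models"]

_CHUNK = 1 << 15

# Per-parameter sampling boxes: initial-count means in [0, 50], rates in
# [0, 2]/yr, probabilities in [0, 1], the escape-rate slope b in [0, 0.5]/yr^2.
_DEFAULT_BOUNDS = {
    "zeroth": {"N_bar": (0.0, 50.0), "kappa": (0.0, 2.0)},
    "model1": {
        "N_bar": (0.0, 50.0),
        "kappa": (0.0, 2.0),
        "lam": (0.0, 2.0),
        "mu": (0.0, 2.0),
        "p_M": (0.0, 1.0),
    },
    "model2": {
        "Ns_bar": (0.0, 50.0),
        "NV_bar": (0.0, 50.0),
        "kappa_s": (0.0, 2.0),
        "kappa_V": (0.0, 2.0),
    },
    "model3": {"N_bar": (0.0, 50.0), "a": (0.0, 2.0), "b": (0.0, 0.5)},
}


def default_bounds(model: str) -> dict:
    return {k: tuple(v) for k, v in _DEFAULT_BOUNDS[model].items()}


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one random-search fit."""

    model: str
    tau: float
    n_samples: int = 1_000_000
    bounds: dict = field(default_factory=dict)
    rng_seed: int = 0
    top_k: int = 5
    polish: bool = False

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        merged = default_bounds(self.model)
        merged.update({k: tuple(v) for k, v in self.bounds.items()})
        for name, (lo, hi) in merged.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
        object.__setattr__(self, "bounds", merged)

    def bounds_array(self):
        names = param_names(self.model)
        lo = np.array([self.bounds[n][0] for n in names])
        hi = np.array([self.bounds[n][1] for n in names])
        return names, lo, hi


@dataclass
class FitResult:
    """Outcome of a random-search fit; params is a name->value mapping."""

    model: str
    params: dict
    tsd: float
    n_samples: int
    rng_seed: int
    tau: float
    top_k: list = field(default_factory=list)
    polished: bool = False

    @property
    def model_params(self):
        return make_params(self.model, self.params)

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model,
            "params": self.params,
            "tsd": self.tsd,
            "n_samples": self.n_samples,
            "rng_seed": self.rng_seed,
            "tau": self.tau,
            "top_k": self.top_k,
            "polished": self.polished,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _data_arrays(curve: RFICurve, tau: float):
    if abs(curve.tau - tau) > 1e-9:
        raise ValueError(
            f"curve is normalized at tau={curve.tau}, fit requested tau={tau}; "
            "normalize_at_tau first"
        )
    keep = curve.times >= tau - 1e-12
    t = curve.times[keep] - tau
    f = curve.rfi[keep]
    if t.size == 0:
        raise ValueError("no data points at or after tau")
    if t[0] <= 1e-9 and abs(f[0] - 1.0) > 1e-6:
        raise ValueError("curve must equal 1 at tau; normalize_at_tau first")
    return t, f


def objective(model_params, curve: RFICurve, tau: float) -> float:
    """Total squared deviation between the model RFI curve and the data."""
    t, f = _data_arrays(curve, tau)
    row = np.array([[getattr(model_params, n) for n in param_names(model_params.model)]])
    pred = survival_batch(model_params.model, row, t)[0]
    return float(np.sum((pred - f) ** 2))


def fit_monte_carlo(config: FitConfig, curve: RFICurve) -> FitResult:
    """Random-search fit: argmin of the tsd over uniform parameter draws."""
    t, f = _data_arrays(curve, config.tau)
    names, lo, hi = config.bounds_array()
    rng = np.random.default_rng(config.rng_seed)
    k = len(names)

    best_tsd = np.inf
    best_row = None
    top: list[tuple[float, np.ndarray]] = []
    remaining = config.n_samples
    while remaining > 0:
        m = min(_CHUNK, remaining)
        remaining -= m
        draws = lo + (hi - lo) * rng.uniform(size=(m, k))
        pred = survival_batch(config.model, draws, t)
        tsd = np.sum((pred - f[None, :]) ** 2, axis=1)
        order = np.argsort(tsd, kind="stable")[: config.top_k]
        for i in order:
            top.append((float(tsd[i]), draws[i].copy()))
        top.sort(key=lambda pair: pair[0])
        top = top[: config.top_k]
        i0 = int(order[0])
        if tsd[i0] < best_tsd:
            best_tsd = float(tsd[i0])
            best_row = draws[i0].copy()

    polished = False
    if config.polish:
        res = minimize(
            lambda x: float(
                np.sum((survival_batch(config.model, x[None, :], t)[0] - f) ** 2)
            ),
            best_row,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
        )
        if res.fun < best_tsd:
            best_tsd, best_row, polished = float(res.fun), res.x, True

    return FitResult(
        model=config.model,
        params={n: float(v) for n, v in zip(names, best_row)},
        tsd=best_tsd,
        n_samples=config.n_samples,
        rng_seed=config.rng_seed,
        tau=config.tau,
        top_k=[{"tsd": ts, "params": dict(zip(names, map(float, row)))} for ts, row in top],
        polished=polished,
    )


def compare_models(
    curve: RFICurve,
    tau: float,
    configs: list[FitConfig] | None = None,
    n_samples: int = 100_000,
    rng_seed: int = 0,
) -> list[FitResult]:
    """Fit all four models with matched budgets/seeds; return results by tsd.

    When configs is omitted, one default FitConfig per model is built with the
    given shared n_samples and seed.
    """
    if configs is None:
        configs = [
            FitConfig(model=m, tau=tau, n_samples=n_samples, rng_seed=rng_seed)
            for m in ("zeroth", "model1", "model2", "model3")
        ]
    results = [fit_monte_carlo(cfg, curve) for cfg in configs]
    return sorted(results, key=lambda r: r.tsd)
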