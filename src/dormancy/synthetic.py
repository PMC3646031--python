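"""Synthetic study-like Kaplan-Meier RFI fixtures.

The real inputs to this kind of analysis are RFI curves digitized from
published long-term follow-up figures: large no-adjuvant-therapy cohorts
(EBCTCG, 6399 patients, 15-year follow-up, growth time tau = 3 y; Chia et
al., 1187 node-negative patients, 10-year follow-up, tau = 1.5 y).  No
machine-readable accession of those curves exists, so every downstream stage
here runs on generated fixtures that emulate such extracted curves: exact
closed-form survival fractions on a figure-like grid, binomial sampling noise
at the study cohort sizes, and optional uniform digitization jitter.

A fixture is written as CSV (time_years, rfi) plus a JSON sidecar holding the
full provenance (scenario, parameters, seed), so any fixture file can be
regenerated exactly from its sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import RFICurve
from .models import ModelParams, escape_survival, make_params

__all__ = ["Scenario", "generate_km_fixture", "preset_scenarios", "scenario_by_name"]


@dataclass(frozen=True)
class Scenario:
    """A study-like data-generating condition.

    noise: 'none' | 'binomial' | 'binomial+jitter'.  Binomial noise perturbs
    each grid value with sd sqrt(f(1-f)/cohort_size); jitter adds uniform
    digitization error of half-width jitter_scale.
    """

    name: str
    model: str
    params: dict
    tau: float
    cohort_size: int
    time_grid: tuple = field(default=())
    noise: str = "binomial"
    jitter_scale: float = 0.0

    def __post_init__(self):
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("time_grid must be non-empty")
        if grid[0] < self.tau - 1e-12:
            raise ValueError("time_grid must start at or after tau")
        if self.noise not in ("none", "binomial", "binomial+jitter"):
            raise ValueError(f"unknown noise mode {self.noise!r}")

    @property
    def model_params(self) -> ModelParams:
        return make_params(self.model, self.params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate_km_fixture(
    scenario: Scenario,
    rng_seed: int,
    out_csv: str | Path | None = None,
) -> RFICurve:
    """Generate one study-like RFI fixture curve.

    Noiseless mode returns the exact closed-form values on the grid.  Noisy
    modes are monotone-corrected by a running minimum (a digitized KM curve
    must be non-increasing) and re-normalized at tau.  If out_csv is given the
    curve is written there together with a provenance JSON sidecar.
    """
    rng = np.random.default_rng(rng_seed)
    times = np.asarray(scenario.time_grid, dtype=float)
    f = np.atleast_1d(escape_survival(scenario.model_params, times - scenario.tau))
    if scenario.noise != "none":
        n = scenario.cohort_size
        f = rng.binomial(n, np.clip(f, 0.0, 1.0)) / n
        if scenario.noise == "binomial+jitter":
            f = f + rng.uniform(-scenario.jitter_scale, scenario.jitter_scale, size=f.size)
        f = np.clip(f, 0.0, 1.0)
        f = np.minimum.accumulate(f)  # running-minimum monotone correction
        if f[0] <= 0:
            raise ValueError("degenerate fixture: f(tau) collapsed to 0 under noise")
        f = np.clip(f / f[0], 0.0, 1.0)  # renormalize at tau
    curve = RFICurve(times=times, rfi=f, tau=scenario.tau)
    if out_csv is not None:
        from .kmio import write_rfi_csv

        out_csv = Path(out_csv)
        write_rfi_csv(curve, out_csv)
        sidecar = {
            "scenario": scenario.to_dict(),
            "rng_seed": int(rng_seed),
            "format": "time_years,rfi CSV",
        }
        out_csv.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return curve


def _yearly(start, stop):
    return tuple(np.arange(start, stop + 1e-9, 1.0))


def _half_yearly(start, stop):
    return tuple(np.arange(start, stop + 1e-9, 0.5))


def preset_scenarios() -> list[Scenario]:
    """Named study-like scenarios spanning peaked and monotone hazards.

    EBCTCG-like presets: tau = 3 y, 6399 patients, yearly grid 3-15 y.
    Chia-like presets: tau = 1.5 y, 1187 patients, half-yearly grid 1.5-10 y.
    'chia_erpos_like' uses a two-step model with almost no one-step
    micrometastases, so its hazard rises from ~0 to an interior maximum (the
    ER+ signature); the others have monotone-decreasing hazards.
    """
    return [
        Scenario(
            name="ebctcg_younger_like",
            model="zeroth",
            params={"N_bar": 1.2, "kappa": 0.25},
            tau=3.0,
            cohort_size=6399,
            time_grid=_yearly(3.0, 15.0),
        ),
        Scenario(
            name="ebctcg_older_like",
            model="model1",
            params={"N_bar": 1.0, "kappa": 0.2, "lam": 0.1, "mu": 0.05, "p_M": 0.3},
            tau=3.0,
            cohort_size=6399,
            time_grid=_yearly(3.0, 15.0),
        ),
        Scenario(
            name="chia_erpos_like",
            model="model2",
            params={"Ns_bar": 1.2, "NV_bar": 0.05, "kappa_s": 0.45, "kappa_V": 0.4},
            tau=1.5,
            cohort_size=1187,
            time_grid=_half_yearly(1.5, 10.0),
        ),
        Scenario(
            name="chia_erneg_like",
            model="zeroth",
            params={"N_bar": 1.0, "kappa": 0.45},
            tau=1.5,
            cohort_size=1187,
            time_grid=_half_yearly(1.5, 10.0),
        ),
        Scenario(
            name="zeroth_flat",
            model="zeroth",
            params={"N_bar": 0.8, "kappa": 0.15},
            tau=3.0,
            cohort_size=6399,
            time_grid=_yearly(3.0, 15.0),
        ),
    ]


def scenario_by_name(name: str) -> Scenario:
    for sc in preset_scenarios():
        if sc.name == name:
            return sc
    known = ", ".join(s.name for s in preset_scenarios())
    raise KeyError(f"unknown scenario {name!r}; known scenarios: {known}")
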