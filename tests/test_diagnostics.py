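"""Hazard decomposition, increase conditions, relapse peaks, burden."""

import math

import numpy as np
import pytest

import dormancy as d
from dormancy.curves import HazardCurve
from dormancy.diagnostics import (
    InapplicableHazardError,
    burden_estimates,
    decomposition_closed_form,
    find_relapse_rate_peak,
    hazard_derivative_decomposition,
    hazard_increase_condition_t0,
    hazard_increasing_at,
    ratio_sweep,
    relapse_peak_ratio,
)
from .conftest import random_params


class TestDecomposition:
    def test_zeroth_closed_form_terms(self):
        # gain = 0; variance = kappa^2 N e^{-kt}; dh/dt = -variance
        p = d.ZerothParams(2.0, 0.3)
        t = 4.0
        gain, var = decomposition_closed_form(p, t)
        expect_var = 0.3**2 * 2.0 * math.exp(-0.3 * t)
        assert gain == 0.0
        assert var == pytest.approx(expect_var)
        assert d.hazard_derivative(p, t) == pytest.approx(-expect_var)

    def test_model3_t0_terms(self):
        p = d.Model3Params(N_bar=1.5, a=0.2, b=0.05)
        gain, var = decomposition_closed_form(p, 0.0)
        assert gain == pytest.approx(0.05 * 1.5)
        assert var == pytest.approx(0.2**2 * 1.5)
        assert d.hazard_derivative(p, 0.0) == pytest.approx(1.5 * (0.05 - 0.04))

    def test_model2_t0_derivative(self):
        p = d.Model2Params(Ns_bar=2.0, NV_bar=0.5, kappa_s=0.4, kappa_V=0.3)
        expect = 0.3 * 0.4 * 2.0 - 0.3**2 * 0.5
        assert d.hazard_derivative(p, 0.0) == pytest.approx(expect)

    @pytest.mark.parametrize("model", ["zeroth", "model1", "model2", "model3"])
    def test_closed_form_identity_random_draws(self, model, rng):
        # dh/dt = gain - variance exactly, via the conditioned moments
        for _ in range(12):
            p = random_params(model, rng)
            for t in (0.0, 1.0, 4.0):
                gain, var = decomposition_closed_form(p, t)
                dh = d.hazard_derivative(p, t)
                assert gain - var == pytest.approx(dh, rel=1e-8, abs=1e-11)

    def test_monte_carlo_identity_single_setting(self):
        p = d.Model2Params(Ns_bar=1.2, NV_bar=0.4, kappa_s=0.5, kappa_V=0.3)
        res = hazard_derivative_decomposition(p, 2.0, n_reps=20_000, rng_seed=77)
        assert abs(res.identity_z) <= 3
        assert res.variance_term >= 0

    def test_conditioning_starvation_propagates(self):
        p = d.ZerothParams(8.0, 2.0)
        with pytest.raises(d.ConditioningError):
            hazard_derivative_decomposition(p, 5.0, n_reps=1000, rng_seed=1)


class TestHazardIncreaseConditions:
    def test_zeroth_never_increasing(self, rng):
        for _ in range(100):
            p = d.ZerothParams(rng.uniform(0.1, 10), rng.uniform(0.01, 2))
            rising, margin = hazard_increasing_at(p, float(rng.uniform(0, 15)))
            assert not rising and margin <= 0

    def test_model3_threshold_b_vs_a_squared(self):
        # b > a^2 at t=0: 0.0099 < 0.01 no rise; 0.0101 > 0.01 rise
        below = d.Model3Params(N_bar=1.0, a=0.1, b=0.0099)
        above = d.Model3Params(N_bar=1.0, a=0.1, b=0.0101)
        assert not hazard_increasing_at(below, 0.0)[0]
        assert hazard_increasing_at(above, 0.0)[0]
        assert not hazard_increase_condition_t0(below)[0]
        assert hazard_increase_condition_t0(above)[0]

    def test_model2_pure_two_step_rises_at_zero(self):
        p = d.Model2Params(Ns_bar=2.0, NV_bar=0.0, kappa_s=0.3, kappa_V=0.3)
        assert hazard_increasing_at(p, 0.0)[0]
        assert hazard_increase_condition_t0(p)[0]

    @pytest.mark.parametrize("model", ["model1", "model2", "model3"])
    def test_t0_condition_agrees_with_numeric_sign(self, model, rng):
        checked = 0
        for _ in range(200):
            p = random_params(model, rng)
            cond, lhs, rhs = hazard_increase_condition_t0(p)
            dh = d.hazard_derivative(p, 0.0)
            if abs(dh) < 1e-9:  # margin band around the threshold
                continue
            checked += 1
            assert cond == (dh > 0), (p, lhs, rhs, dh)
        assert checked > 150


class TestRelapseRatePeak:
    def test_zeroth_never_peaks(self, rng):
        for _ in range(100):
            p = d.ZerothParams(rng.uniform(0.1, 10), rng.uniform(0.02, 2))
            assert find_relapse_rate_peak(p, 30.0) is None

    def test_model2_pure_two_step_has_interior_peak(self):
        p = d.Model2Params(Ns_bar=5.0, NV_bar=0.0, kappa_s=0.2, kappa_V=0.2)
        peak = find_relapse_rate_peak(p, 30.0)
        assert peak is not None and 0 < peak < 30

    def test_model3_b_zero_reduces_to_zeroth(self):
        assert find_relapse_rate_peak(d.Model3Params(2.0, 0.3, 0.0), 30.0) is None

    def test_peak_ratio_threshold_is_one(self):
        # peak iff dh/dt(0) > h(0)^2 <=> ratio < 1
        base = {"Ns_bar": 2.0, "kappa_s": 0.3, "kappa_V": 0.25}
        just_below = d.Model2Params(NV_bar=0.9, **base)
        r = relapse_peak_ratio(just_below)
        dr0 = d.hazard_derivative(just_below, 0.0) - d.hazard(just_below, 0.0) ** 2
        assert (r < 1) == (dr0 > 0)


class TestRatioSweep:
    BASES = {
        "model1": {"N_bar": 1.0, "kappa": 0.3, "lam": 0.02, "mu": 1.2, "p_M": 0.8},
        "model2": {"Ns_bar": 2.0, "NV_bar": 1.0, "kappa_s": 0.3, "kappa_V": 0.25},
        "model3": {"N_bar": 1.0, "a": 0.1, "b": 0.05},
    }

    @pytest.mark.parametrize("model", ["model1", "model2", "model3"])
    def test_fig3_pattern(self, model):
        """No peak when the inequality fails 2x; peaks at ratios 1/5, 1/25."""
        entries = ratio_sweep(model, self.BASES[model])
        flags = {e["target_ratio"]: e["has_interior_peak"] for e in entries if e["reachable"]}
        assert flags[2.0] is False
        assert flags[0.2] is True and flags[0.04] is True

    @pytest.mark.parametrize("model", ["model1", "model2", "model3"])
    def test_ratio_achieved_precisely(self, model):
        for e in ratio_sweep(model, self.BASES[model]):
            assert e["reachable"]
            assert abs(e["achieved_ratio"] - e["target_ratio"]) <= 1e-6 * e["target_ratio"]

    @pytest.mark.parametrize("model", ["model1", "model2", "model3"])
    def test_stronger_violation_gives_more_prominent_peak(self, model):
        """Lowering the swept parameter makes the peak more pronounced.

        Prominence is measured relative to the initial relapse rate r(0+):
        reducing the swept parameter also shrinks the overall relapse
        intensity, so the absolute peak height can fall even as the peak
        becomes far more marked against the early rate.
        """
        entries = {e["target_ratio"]: e for e in ratio_sweep(model, self.BASES[model])}
        e5, e25 = entries[0.2], entries[0.04]

        def prominence(e):
            peak_r = np.interp(e["peak_time"], e["times"], e["relapse_rate"])
            r0 = max(e["relapse_rate"][1], 1e-12)  # first grid point past 0
            return peak_r / r0

        assert prominence(e25) > prominence(e5)

    def test_unreachable_ratio_reported_not_raised(self):
        base = {"N_bar": 1.0, "kappa": 0.3, "lam": 1.5, "mu": 1.2, "p_M": 0.8}
        entries = ratio_sweep("model1", base, target_ratios=(0.04,))
        assert entries[0]["reachable"] is False
        assert "unreachable" in entries[0]["reason"]


class TestBurdenEstimates:
    def test_exact_on_analytic_zeroth_hazard(self):
        """mean = h/kappa, var = -h'/kappa^2 recover the conditioned moments."""
        p = d.ZerothParams(2.0, 0.1)
        t = np.linspace(0.0, 25.0, 401)
        hz = HazardCurve(times=t, h=np.asarray(d.hazard(p, t)))
        ts = np.array([5.0, 10.0, 20.0])
        ests = burden_estimates(hz, 0.1, ts, dh_dt=np.asarray(d.hazard_derivative(p, ts)))
        for est, tt in zip(ests, ts):
            expect = 2.0 * math.exp(-0.1 * tt)  # conditioned Poisson mean = var
            assert abs(est.mean_n - expect) / expect < 1e-6
            assert abs(est.var_n - expect) / expect < 1e-6

    def test_boundary_constant_hazard(self):
        # h = 0.02/yr with kappa = 1/50 yr: exactly one micrometastasis
        hz = HazardCurve(times=np.array([0.0, 20.0]), h=np.array([0.02, 0.02]))
        est = burden_estimates(hz, 0.02, [10.0])[0]
        assert est.mean_n == pytest.approx(1.0)
        assert est.var_n == pytest.approx(0.0)

    def test_zero_hazard_zero_burden(self):
        hz = HazardCurve(times=np.array([0.0, 20.0]), h=np.zeros(2))
        assert burden_estimates(hz, 0.5, [5.0])[0].mean_n == 0.0

    def test_increasing_hazard_window_rejected(self):
        hz = HazardCurve(times=np.array([0.0, 5.0, 10.0]), h=np.array([0.1, 0.2, 0.3]))
        with pytest.raises(InapplicableHazardError):
            burden_estimates(hz, 0.1, [2.0, 8.0])

    def test_invalid_kappa_rejected(self):
        hz = HazardCurve(times=np.array([0.0, 5.0]), h=np.array([0.1, 0.05]))
        with pytest.raises(ValueError):
            burden_estimates(hz, 0.0, [2.0])
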