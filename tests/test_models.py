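"""Closed-form survival, hazard, and conditioned-moment theory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

import dormancy as d
from dormancy.models import (
    _q_two_stage_equal,
    _q_two_stage_general,
    zeroth_hazard_counts,
    zeroth_survival_counts,
)
from .conftest import random_params

GRID = np.linspace(0.0, 30.0, 100)


class TestEscapeSurvival:
    def test_no_micrometastases_never_relapse(self):
        assert d.escape_survival(d.ZerothParams(N_bar=0, kappa=0.3), 5.0) == 1.0

    def test_zeroth_closed_form_value(self):
        # Poisson-mixed one-step escape: S(t) = exp(-N(1 - e^{-kt}))
        val = d.escape_survival(d.ZerothParams(N_bar=1, kappa=0.1), 10.0)
        assert val == pytest.approx(math.exp(-(1 - math.exp(-1))), abs=1e-15)

    def test_survival_starts_at_one(self, reference_params):
        for p in reference_params.values():
            assert d.escape_survival(p, 0.0) == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("model", ["zeroth", "model1", "model2", "model3"])
    def test_survival_bounded_and_nonincreasing(self, model, rng):
        for _ in range(25):
            p = random_params(model, rng)
            s = d.escape_survival(p, GRID)
            assert np.all(s >= 0) and np.all(s <= 1)
            assert np.all(np.diff(s) <= 1e-12)

    def test_negative_time_rejected(self, reference_params):
        with pytest.raises(ValueError):
            d.escape_survival(reference_params["zeroth"], -1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            d.ZerothParams(N_bar=-1, kappa=0.1)
        with pytest.raises(ValueError):
            d.Model1Params(N_bar=1, kappa=0.1, lam=0.1, mu=0.1, p_M=1.5)
        with pytest.raises(ValueError):
            d.Model3Params(N_bar=1, a=-0.1, b=0.0)

    def test_all_zero_rates_degenerate(self):
        # degenerate all-zero parameters: survival 1, hazard 0, no errors
        for p in (
            d.ZerothParams(2.0, 0.0),
            d.Model1Params(2.0, 0.0, 0.0, 0.0, 0.5),
            d.Model2Params(2.0, 2.0, 0.0, 0.0),
            d.Model3Params(2.0, 0.0, 0.0),
        ):
            assert np.all(d.escape_survival(p, GRID) == 1.0)
            assert np.all(np.asarray(d.hazard(p, GRID)) == 0.0)


class TestReductionLimits:
    """Each richer model collapses exactly onto the Zeroth model."""

    @pytest.mark.parametrize(
        "p, zeroth",
        [
            (d.Model1Params(2.0, 0.3, 0.0, 0.0, 0.5), d.ZerothParams(2.0, 0.3)),
            (d.Model2Params(0.0, 2.0, 0.7, 0.3), d.ZerothParams(2.0, 0.3)),
            (d.Model3Params(2.0, 0.3, 0.0), d.ZerothParams(2.0, 0.3)),
        ],
        ids=["model1_mu_lam_zero", "model2_no_two_step", "model3_constant_rate"],
    )
    def test_reduction(self, p, zeroth):
        err = np.abs(d.escape_survival(p, GRID) - d.escape_survival(zeroth, GRID))
        assert err.max() <= 1e-10

    def test_model2_equal_rate_continuity(self):
        # hypoexponential tail is continuous as kappa_s -> kappa_V
        t = np.linspace(0, 30, 101)
        ks, kV = 0.2, 0.2 + 1e-6
        gap = np.abs(
            _q_two_stage_general(ks, kV, t) - _q_two_stage_equal(0.5 * (ks + kV), t)
        )
        assert gap.max() <= 1e-8


class TestRFICurve:
    def test_normalization_point(self, reference_params):
        for p in reference_params.values():
            curve = d.rfi_curve(p, tau=3.0, times=[3.0])
            assert curve.rfi[0] == pytest.approx(1.0)

    def test_value_matches_survival_shifted_by_tau(self):
        p = d.ZerothParams(1.0, 0.1)
        curve = d.rfi_curve(p, tau=3.0, times=[13.0])
        assert curve.rfi[0] == pytest.approx(math.exp(-(1 - math.exp(-1))), abs=1e-14)

    def test_times_before_tau_rejected(self, reference_params):
        with pytest.raises(ValueError):
            d.rfi_curve(reference_params["zeroth"], tau=3.0, times=[2.0, 4.0])

    def test_nonincreasing(self, reference_params):
        times = np.linspace(3, 20, 40)
        for p in reference_params.values():
            curve = d.rfi_curve(p, tau=3.0, times=times)
            assert curve.is_monotone


class TestHazard:
    def test_zeroth_initial_hazard_is_kappa_N(self):
        assert d.hazard(d.ZerothParams(1.0, 0.1), 0.0) == pytest.approx(0.1)

    def test_zeroth_closed_form(self):
        p = d.ZerothParams(1.7, 0.23)
        t = np.linspace(0, 20, 50)
        assert d.hazard(p, t) == pytest.approx(1.7 * 0.23 * np.exp(-0.23 * t))

    def test_model2_two_step_only_starts_at_zero(self):
        # with no one-step micrometastases, escape needs a prior s->V event
        assert d.hazard(d.Model2Params(2.0, 0.0, 0.2, 0.2), 0.0) == 0.0

    @pytest.mark.parametrize("model", ["zeroth", "model1", "model2", "model3"])
    def test_matches_log_survival_derivative(self, model, rng):
        # h = -d ln S / dt, central difference
        eps = 1e-6
        for _ in range(10):
            p = random_params(model, rng)
            for t in (0.5, 2.0, 9.0):
                num = -(
                    math.log(d.escape_survival(p, t + eps))
                    - math.log(d.escape_survival(p, t - eps))
                ) / (2 * eps)
                assert d.hazard(p, t) == pytest.approx(num, rel=1e-6, abs=1e-9)

    @pytest.mark.parametrize("model", ["zeroth", "model1", "model2", "model3"])
    def test_analytic_derivative_matches_finite_difference(self, model, rng):
        eps = 1e-5
        for _ in range(10):
            p = random_params(model, rng)
            for t in (0.5, 2.0, 9.0):
                num = (d.hazard(p, t + eps) - d.hazard(p, t - eps)) / (2 * eps)
                assert d.hazard_derivative(p, t) == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestRelapseRate:
    def test_zero_mean_count_gives_zero_rate(self):
        assert np.all(
            np.asarray(d.relapse_rate(d.ZerothParams(0.0, 0.5), GRID)) == 0.0
        )

    def test_zeroth_rate_strictly_decreasing(self, rng):
        for _ in range(20):
            p = d.ZerothParams(rng.uniform(0.2, 5), rng.uniform(0.05, 1))
            r = d.relapse_rate(p, np.linspace(0, 30, 400))
            assert np.all(np.diff(r) < 0)

    def test_total_relapse_probability(self):
        # integral of r over [0, inf) = 1 - exp(-N) for the Zeroth model
        p = d.ZerothParams(1.4, 0.3)
        total, err = quad(lambda t: d.relapse_rate(p, t), 0, np.inf)
        assert total == pytest.approx(1 - math.exp(-1.4), abs=1e-8)


class TestConditionalMoments:
    def test_zeroth_conditioned_poisson_thinning(self):
        p = d.ZerothParams(2.0, 0.1)
        mean, var = d.conditional_moments(p, 5.0)["total"]
        expect = 2.0 * math.exp(-0.5)
        assert mean == pytest.approx(expect) and var == pytest.approx(expect)

    def test_initial_moments_equal_poisson_means(self, reference_params):
        mom = d.conditional_moments(reference_params["model2"], 0.0)
        assert mom["s"][0] == pytest.approx(1.2)
        assert mom["V"][0] == pytest.approx(0.4)
        mom1 = d.conditional_moments(reference_params["model1"], 0.0)
        assert mom1["total"][0] == pytest.approx(1.5)
        assert mom1["total"][1] == pytest.approx(1.5)

    @pytest.mark.parametrize("model", ["zeroth", "model1", "model2", "model3"])
    def test_hazard_equals_intensity_times_mean(self, model, rng):
        # h = kappa E[n] (zeroth/1), kappa_V E[n_V] (2), (a+bt) E[n] (3)
        for _ in range(10):
            p = random_params(model, rng)
            for t in (0.0, 1.5, 6.0):
                mom = d.conditional_moments(p, t)
                if model in ("zeroth", "model1"):
                    h = p.kappa * mom["total"][0]
                elif model == "model2":
                    h = p.kappa_V * mom["V"][0]
                else:
                    h = (p.a + p.b * t) * mom["total"][0]
                assert h == pytest.approx(d.hazard(p, t), rel=1e-9, abs=1e-12)

    def test_model1_permissive_moments_match_ode_oracle(self):
        """Generating-function ODE system integrated numerically.

        q' = mu q^2 - R q + lam;  m' = (2 mu q - R) m;  v' = 2 mu m^2 +
        (2 mu q - R) v, with q(0)=1, m(0)=1, v(0)=0.  Conditional moments for
        Poisson(N p_M) ancestors: mean = N p_M m, var = N p_M (v + m).
        """
        p = d.Model1Params(N_bar=2.0, kappa=0.25, lam=0.15, mu=0.4, p_M=1.0)
        R = p.kappa + p.lam + p.mu

        def rhs(t, y):
            q, m, v = y
            return [
                p.mu * q * q - R * q + p.lam,
                (2 * p.mu * q - R) * m,
                2 * p.mu * m * m + (2 * p.mu * q - R) * v,
            ]

        sol = solve_ivp(rhs, (0, 8.0), [1.0, 1.0, 0.0], rtol=1e-11, atol=1e-13,
                        dense_output=True)
        for t in (0.5, 2.0, 8.0):
            q, m, v = sol.sol(t)
            mean, var = d.conditional_moments(p, t)["permissive"]
            assert mean == pytest.approx(p.N_bar * m, rel=1e-8)
            assert var == pytest.approx(p.N_bar * (v + m), rel=1e-7)


class TestZerothCountDistributions:
    """The Zeroth hazard is non-increasing for ANY initial count distribution."""

    DISTS = [
        ("poisson", 2.0),
        ("fixed", 3),
        ("mixture", [(0, 0.3), (1, 0.4), (5, 0.3)]),
    ]

    def test_pgf_survival_forms(self):
        t = 4.0
        q = math.exp(-0.3 * t)
        assert zeroth_survival_counts(("fixed", 3), 0.3, t) == pytest.approx(q**3)
        assert zeroth_survival_counts(("poisson", 2.0), 0.3, t) == pytest.approx(
            math.exp(2.0 * (q - 1))
        )

    @pytest.mark.parametrize("dist", DISTS, ids=["poisson", "fixed", "mixture"])
    def test_hazard_nonincreasing(self, dist):
        t = np.linspace(0, 40, 500)
        h = zeroth_hazard_counts(dist, 0.3, t)
        assert np.all(np.diff(h) <= 1e-12)

    @pytest.mark.parametrize("dist", DISTS, ids=["poisson", "fixed", "mixture"])
    def test_hazard_matches_survival_log_derivative(self, dist):
        eps = 1e-6
        for t in (0.5, 3.0, 10.0):
            num = -(
                math.log(zeroth_survival_counts(dist, 0.3, t + eps))
                - math.log(zeroth_survival_counts(dist, 0.3, t - eps))
            ) / (2 * eps)
            assert zeroth_hazard_counts(dist, 0.3, t) == pytest.approx(num, rel=1e-6)


class TestBatchEvaluation:
    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from(["zeroth", "model1", "model2", "model3"]))
    def test_batch_matches_scalar_path(self, seed, model):
        rng = np.random.default_rng(seed)
        p = random_params(model, rng)
        row = np.array([[getattr(p, n) for n in d.param_names(model)]])
        t = np.linspace(0, 25, 40)
        batch = d.survival_batch(model, row, t)[0]
        scalar = d.escape_survival(p, t)
        assert np.max(np.abs(batch - scalar)) <= 1e-11

    def test_serialization_roundtrip(self, reference_params):
        for model, p in reference_params.items():
            mapping = {n: getattr(p, n) for n in d.param_names(model)}
            assert d.make_params(model, mapping) == p
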