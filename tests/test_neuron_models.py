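"""Neuron model library: map/ODE dynamics, resets, tabulation, presets."""

import math

import numpy as np
import pytest

from hybridclamp.calibration import characterize_model
from hybridclamp.integrators import IntegratorSpec, integrate_step
from hybridclamp.neuron_models import (
    ConductanceModel,
    HindmarshRose,
    HindmarshRoseParams,
    Izhikevich,
    IzhikevichParams,
    LookupTable,
    ModelError,
    RulkovMap,
    RulkovParams,
    from_preset,
    load_presets,
    rulkov_step,
    tabulate,
)

STOCK_PRESETS = ["rulkov_burster", "izhikevich_burster", "hindmarsh_rose_burster",
                 "ghigliazza_holmes_burster", "wang_burster"]


class TestRulkov:
    def test_fixed_point_is_invariant(self):
        # 4/(1-(-1)) - 3 = -1 and x+1 = 0: both maps stationary
        p = RulkovParams(alpha=4.0, sigma=0.0, mu=0.001)
        state = (-1.0, -1.0, -3.0)
        x, x_prev, y = rulkov_step(p, state)
        assert (x, y) == (-1.0, -3.0)

    def test_zero_mu_freezes_slow_variable(self):
        p = RulkovParams(alpha=4.5, sigma=0.3, mu=0.0)
        state = (0.5, -1.0, -2.8)
        for _ in range(1000):
            state = rulkov_step(p, state)
            assert state[2] == -2.8

    def test_non_finite_state_rejected(self):
        with pytest.raises(ModelError):
            rulkov_step(RulkovParams(), (float("nan"), -1.0, -2.8))

    def test_negative_mu_rejected(self):
        with pytest.raises(ModelError):
            RulkovParams(mu=-1e-3)

    def test_trajectory_matches_literal_transcription(self):
        """10^5 iterations bit-identical to an independently coded literal
        transcription of the piecewise map (brute-force oracle)."""
        p = RulkovParams()  # stock bursting defaults

        def oracle(alpha, sigma, mu, x, x_old, y, n):
            traj = []
            for _ in range(n):
                if x <= 0.0:
                    x_next = alpha / (1.0 - x) + y
                elif (x < alpha + y) and (x_old <= 0.0):
                    x_next = alpha + y
                else:
                    x_next = -1.0
                y_next = y - mu * (x + 1.0) + mu * sigma
                x_old, x, y = x, x_next, y_next
                traj.append((x, y))
            return traj

        model = RulkovMap(p)
        state = model.initial_state()
        ours = []
        for _ in range(100_000):
            state = model.map_step(state)
            ours.append((state[0], state[2]))
        theirs = oracle(p.alpha, p.sigma, p.mu, *model.initial_state()[:1],
                        model.initial_state()[1], model.initial_state()[2],
                        100_000)
        assert ours == theirs  # bit-identical


class TestIzhikevich:
    def test_v_nullcline_roots(self):
        """With u = b v and I = 0, dv/dt = 0 exactly at the roots of
        0.04 v^2 + (5-b) v + 140 = 0 (quadratic-root oracle)."""
        b = 0.2
        model = Izhikevich(IzhikevichParams(b=b, I=0.0))
        disc = (5.0 - b) ** 2 - 4 * 0.04 * 140.0
        roots = [(-(5.0 - b) + s * math.sqrt(disc)) / (2 * 0.04) for s in (1, -1)]
        assert sorted(round(r, 6) for r in roots) == [-70.0, -50.0]
        for v in roots:
            dv, _ = model.derivs(0.0, (v, b * v))
            assert abs(dv) < 1e-9

    @pytest.mark.parametrize("state,expect_fired,expect_state", [
        ((35.0, -10.0), True, (-50.0, -8.0)),
        ((-60.0, -12.0), False, (-60.0, -12.0)),
        ((30.0, 0.0), True, (-50.0, 2.0)),  # boundary inclusive
    ])
    def test_reset_rule(self, state, expect_fired, expect_state):
        model = Izhikevich(IzhikevichParams(c=-50.0, d=2.0, peak=30.0))
        new, fired = model.discrete_events(state)
        assert fired is expect_fired
        assert new == expect_state

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ModelError):
            Izhikevich().derivs(0.0, (1.0, 2.0, 3.0))


class TestHindmarshRose:
    def test_equilibrium_found_by_root_oracle(self):
        """All derivatives vanish (< 1e-9) at the root of the equilibrium
        system located by an independent root finder."""
        from scipy.optimize import fsolve

        model = HindmarshRose(HindmarshRoseParams(b=3.0, I=3.0, r=0.001,
                                                  s=4.0, x_rest=-1.6))
        root = fsolve(lambda y: model.derivs(0.0, tuple(y)), (-1.5, -10.0, 2.0),
                      full_output=False, xtol=1e-13)
        d = model.derivs(0.0, tuple(root))
        assert max(abs(v) for v in d) < 1e-9

    def test_derivatives_finite_for_finite_state(self):
        model = HindmarshRose()
        for state in [(-1e3, 1e3, -1e3), (0.0, 0.0, 0.0), (2.0, -30.0, 4.0)]:
            assert all(math.isfinite(v) for v in model.derivs(0.0, state))


class TestConductance:
    @pytest.mark.parametrize("preset", ["ghigliazza_holmes_burster", "wang_burster"])
    def test_gating_derivatives_vanish_at_steady_state(self, preset):
        model = from_preset(preset)
        v = -35.0
        if model.params.variant == "wang":
            from hybridclamp.neuron_models import WANG_RATE_FNS as R, boltzmann

            h = R["alpha_h"](v) / (R["alpha_h"](v) + R["beta_h"](v))
            n = R["alpha_n"](v) / (R["alpha_n"](v) + R["beta_n"](v))
            z = boltzmann(v, model.params.gates["z"]["half"],
                          model.params.gates["z"]["slope"])
            d = model.derivs(0.0, (v, h, n, z))
        else:
            from hybridclamp.neuron_models import boltzmann

            g = model.params.gates
            n = boltzmann(v, g["n"]["half"], g["n"]["slope"])
            s = boltzmann(v, g["s"]["half"], g["s"]["slope"])
            d = model.derivs(0.0, (v, n, s))
        assert all(abs(x) < 1e-12 for x in d[1:])

    def test_currents_balance_capacitive_current_at_equilibrium(self):
        """At the full-system equilibrium located by an independent root
        finder, the ionic currents sum exactly to the injected drive."""
        from scipy.optimize import brentq

        model = from_preset("ghigliazza_holmes_burster")
        p = model.params
        from hybridclamp.neuron_models import boltzmann

        gates = p.gates

        def dv_at(v):
            n = boltzmann(v, gates["n"]["half"], gates["n"]["slope"])
            s = boltzmann(v, gates["s"]["half"], gates["s"]["slope"])
            return model.derivs(0.0, (v, n, s))[0]

        v = brentq(dv_at, -10.0, 20.0, xtol=1e-13)
        n = boltzmann(v, gates["n"]["half"], gates["n"]["slope"])
        s = boltzmann(v, gates["s"]["half"], gates["s"]["slope"])
        ionic = (p.g["Ca"] * boltzmann(v, p.gates["m"]["half"],
                                       p.gates["m"]["slope"]) * (v - p.E["Ca"])
                 + p.g["K"] * n * (v - p.E["K"])
                 + p.g["KS"] * s * (v - p.E["K"])
                 + p.g["L"] * (v - p.E["L"]))
        assert abs(ionic - p.I) < 1e-8  # C dv/dt = I - ionic = 0

    def test_gating_stays_bounded_over_a_burst(self):
        for preset in ["ghigliazza_holmes_burster", "wang_burster"]:
            model = from_preset(preset)
            spec = IntegratorSpec("rk4", model.hints.dt)
            state, t = model.initial_state(), 0.0
            horizon = model.hints.min_gap * 10
            for _ in range(int(horizon / model.hints.dt)):
                state, _ = integrate_step(spec, model.derivs, state, t)
                t += model.hints.dt
                assert model.gating_in_bounds(state)


class TestLookupTable:
    def test_identity_function_is_exact_everywhere(self):
        table = tabulate(lambda x: x, -3.0, 5.0, 17)
        for x in np.linspace(-3.0, 5.0, 101):
            assert table(float(x)) == pytest.approx(x, abs=1e-12)

    def test_node_values_reproduce_function_exactly(self):
        table = tabulate(math.exp, -10.0, 0.0, 101)
        for x in table.nodes:
            assert table(x) == math.exp(x)

    def test_exp_interpolation_error_below_dense_scan_bound(self):
        """Max abs error over a 10x denser scan is below the analytic
        linear-interpolation bound h^2/8 * max|f''| (dense-scan oracle)."""
        lo, hi, n = -10.0, 0.0, 10001
        table = tabulate(math.exp, lo, hi, n)
        h = (hi - lo) / (n - 1)
        bound = h * h / 8.0 * math.exp(0.0)
        xs = np.linspace(lo, hi, 10 * (n - 1) + 1)
        err = max(abs(table(float(x)) - math.exp(float(x))) for x in xs)
        assert err <= bound * (1 + 1e-9)

    def test_out_of_range_queries_clamp(self):
        table = tabulate(math.exp, -2.0, 2.0, 11)
        assert table(-100.0) == math.exp(-2.0)
        assert table(100.0) == math.exp(2.0)

    def test_non_finite_value_rejected_with_node(self):
        with pytest.raises(ValueError, match="node"):
            # the x = 0 node evaluates to +inf
            tabulate(lambda x: float("inf") if x == 0.0 else 1.0 / x,
                     -1.0, 1.0, 21)

    def test_tabulated_nonlinearities_match_direct_to_1e6_relative(self):
        model = from_preset("wang_burster")
        tab = model.tabulated(-100.0, 60.0, 10001)
        for name, fn in model.nonlinearities().items():
            for v in np.linspace(-90.0, 50.0, 500):
                direct = fn(float(v))
                approx = tab._tables[name](float(v))
                assert abs(approx - direct) <= 1e-6 * max(1.0, abs(direct))

    def test_tabulated_trajectory_tracks_direct_over_one_burst(self):
        model = from_preset("ghigliazza_holmes_burster")
        tab = model.tabulated(-100.0, 60.0, 20001)
        spec = IntegratorSpec("rk4", model.hints.dt)
        s1, s2, t = model.initial_state(), model.initial_state(), 0.0
        dur = 1200.0  # one burst period of the stock preset
        devs = []
        for _ in range(int(dur / model.hints.dt)):
            s1, _ = integrate_step(spec, model.derivs, s1, t)
            s2, _ = integrate_step(spec, tab.derivs, s2, t)
            t += model.hints.dt
            devs.append(abs(s1[0] - s2[0]))
        assert max(devs) < 0.5  # mV, over one burst


class TestPresets:
    def test_registry_round_trips_through_reader(self):
        presets = load_presets("neurons")
        assert set(STOCK_PRESETS) <= set(presets)
        for name in STOCK_PRESETS:
            model = from_preset(name)
            assert model.kind in ("map", "ode")

    @pytest.mark.parametrize("preset", STOCK_PRESETS)
    def test_every_stock_preset_is_in_a_bursting_regime(self, preset):
        """The burst detector finds >= 3 bursts in each preset's free run."""
        ch = characterize_model(from_preset(preset))
        assert ch.n_bursts >= 3
        assert 0.0 < ch.burst_duration < ch.burst_period

    def test_overrides_are_applied(self):
        model = from_preset("rulkov_burster", {"sigma": 0.01})
        assert model.params.sigma == 0.01
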