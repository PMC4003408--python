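"""Engine semantics: integration, transitions, routing, logging."""

import numpy as np
import pytest

from spineml import (ConnectivitySpec, Experiment, FixedValue, InputDriver,
                     LogRequest, NetworkModel, PropertySpec, elaborate,
                     file_loader, resolve_references, simulate)
from spineml.engine import integrator_step
from spineml.expr import parse_expression as pe
from spineml.network import ComponentInstanceSet, GenericInput, Group

from conftest import (gap_junction_flat, lif_population, single_lif_flat,
                      wu_psc_chain)


def lif_isi_analytic(i_na, v_rest=-60.0, v_thresh=-50.0, v_reset=-60.0,
                     tau_m=20.0, c_m=1.0, tau_ref=5.0):
    """Closed-form inter-spike period of the LIF under constant current."""
    v_inf = v_rest + (i_na / c_m) * tau_m
    return tau_ref + tau_m * np.log((v_inf - v_reset) / (v_inf - v_thresh))


class TestIntegratorStep:
    def test_zero_derivative_leaves_state_unchanged(self):
        for method in ("forward_euler", "rk4"):
            out = integrator_step([("x", pe("0"))], {"x": 3.0, "y": 1.0},
                                  {"t": 0.0}, 0.1, method)
            assert out["x"] == 3.0 and out["y"] == 1.0

    def test_single_euler_step_of_unit_slope(self):
        out = integrator_step([("v", pe("1"))], {"v": 0.0}, {"t": 0.0},
                              0.1, "forward_euler")
        assert out["v"] == pytest.approx(0.1)

    def test_variables_without_derivatives_held(self):
        out = integrator_step([("v", pe("1"))], {"v": 0.0, "w": 5.0},
                              {"t": 0.0}, 0.1, "rk4")
        assert out["w"] == 5.0

    @pytest.mark.parametrize("method,expected_order",
                             [("forward_euler", 1), ("rk4", 4)])
    def test_convergence_order_on_exponential_decay(self, method,
                                                    expected_order):
        # dv/dt = (v_rest - v)/tau_m against the analytic exponential
        tau, v0, T = 10.0, 10.0, 20.0
        errs = []
        dts = [0.2, 0.1, 0.05]
        for dt in dts:
            v = np.array([v0])
            for i in range(int(round(T / dt))):
                out = integrator_step(
                    [("v", pe("(0 - v)/tau_m"))], {"v": v},
                    {"tau_m": tau, "t": i * dt}, dt, method)
                v = out["v"]
            errs.append(abs(float(v[0]) - v0 * np.exp(-T / tau)))
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert abs(slope - expected_order) < 0.3


class TestLIFDynamics:
    def test_resting_neuron_is_a_fixed_point(self, component_dir):
        flat = single_lif_flat(component_dir, v_init=-60.0)
        exp = Experiment("", 0.1, 0.1,
                         logs=[LogRequest("vm", "N", "v"),
                               LogRequest("s", "N", "spike")])
        logs = simulate(flat, exp)
        assert np.all(logs.frames["vm"]["value"] == -60.0)
        assert len(logs.frames["s"]) == 0

    @pytest.mark.parametrize("dt", [0.1, 0.01])
    def test_isi_matches_closed_form(self, component_dir, dt):
        flat = single_lif_flat(component_dir, v_init=-60.0)
        exp = Experiment(
            "", 0.3, dt,
            inputs=[InputDriver("constant_current", "N", "I_Syn", value=1.0)],
            logs=[LogRequest("s", "N", "spike")])
        logs = simulate(flat, exp)
        isis = np.diff(logs.frames["s"]["t_ms"].to_numpy())
        assert len(isis) >= 5
        assert abs(isis.mean() - lif_isi_analytic(1.0)) < 2 * dt

    def test_refractory_lower_bounds_every_isi(self, component_dir):
        flat = single_lif_flat(component_dir, v_init=-50.5)
        exp = Experiment(
            "", 0.5, 0.1,
            inputs=[InputDriver("constant_current", "N", "I_Syn", value=2.0)],
            logs=[LogRequest("s", "N", "spike")])
        logs = simulate(flat, exp)
        isis = np.diff(logs.frames["s"]["t_ms"].to_numpy())
        assert np.all(isis >= 5.0)


class TestImpulseChain:
    def test_psc_decay_matches_exponential(self, component_dir):
        tau = 5.0
        flat = wu_psc_chain(component_dir, w=2.5, tau_syn=tau)
        exp = Experiment(
            "", 0.1, 0.1, integrator="rk4",
            inputs=[InputDriver("explicit_spike_source", "wu", "spike_in",
                                spike_times_ms=(10.0,))],
            logs=[LogRequest("i", "psc", "I_Syn")])
        logs = simulate(flat, exp)
        df = logs.frames["i"]
        v = df["value"].to_numpy()
        t = df["t_ms"].to_numpy()
        k = int(v.argmax())
        assert v[k] == pytest.approx(2.5)  # impulse of exactly w
        expected = v[k] * np.exp(-(t[k:] - t[k]) / tau)
        assert np.max(np.abs(v[k:] - expected) / v[k]) < 1e-3

    def test_impulse_delay_rounded_to_nearest_step(self, component_dir):
        dt = 0.1
        base = None
        for delay in (0.0, 0.25, 0.34):
            flat = wu_psc_chain(component_dir, w=1.0, tau_syn=1e9,
                                delay_ms=delay)
            exp = Experiment(
                "", 0.01, dt,
                inputs=[InputDriver("explicit_spike_source", "wu", "spike_in",
                                    spike_times_ms=(2.0,))],
                logs=[LogRequest("i", "psc", "I_Syn")])
            logs = simulate(flat, exp)
            df = logs.frames["i"]
            t_first = df.loc[df["value"] > 0.5, "t_ms"].iloc[0]
            if delay == 0.0:
                base = t_first
            else:
                # floor(d/dt + 0.5) extra steps: 0.25 -> 3, 0.34 -> 3
                assert t_first == pytest.approx(base + 0.3)

    def test_event_conservation(self, component_dir):
        # every delivered impulse adds exactly w to a non-decaying PSC
        flat = wu_psc_chain(component_dir, w=1.0, tau_syn=1e12)
        times = tuple(np.arange(1.0, 90.0, 3.7))
        exp = Experiment(
            "", 0.1, 0.1,
            inputs=[InputDriver("explicit_spike_source", "wu", "spike_in",
                                spike_times_ms=times)],
            logs=[LogRequest("i", "psc", "I_Syn")])
        logs = simulate(flat, exp)
        final = logs.frames["i"]["value"].iloc[-1]
        assert final == pytest.approx(len(times))


class TestReducePorts:
    def test_reduce_port_sums_k_identical_sources(self, component_dir):
        # k PSC instances, each frozen at I_Syn = x, all feeding one neuron
        k, x = 5, 0.25
        net = NetworkModel(
            populations=[lif_population(size=1)],
            groups=[Group(ComponentInstanceSet(
                "psc", "ExpPSC.xml", k,
                [PropertySpec("tau_syn", FixedValue(1e12)),
                 PropertySpec("I_Syn", FixedValue(x))]))],
            inputs=[GenericInput("psc", "N", "I_Syn", "I_Syn",
                                 ConnectivitySpec("all_to_all"))])
        res = resolve_references(net, file_loader(component_dir))
        assert not res.diagnostics, res.diagnostics
        flat = elaborate(res)
        exp = Experiment("", 0.01, 0.1,
                         logs=[LogRequest("isyn", "N", "I_Syn")])
        logs = simulate(flat, exp)
        assert np.allclose(logs.frames["isyn"]["value"], k * x)

    def test_reduce_port_zero_filled_without_arrivals(self, component_dir):
        flat = single_lif_flat(component_dir)
        exp = Experiment("", 0.01, 0.1,
                         logs=[LogRequest("isyn", "N", "I_Syn")])
        logs = simulate(flat, exp)
        assert np.all(logs.frames["isyn"]["value"] == 0.0)


class TestOrderingAndDeterminism:
    def test_regime_switch_before_next_derivatives(self, component_dir):
        # after the reset the voltage is pinned at v_reset for the whole
        # refractory period: the switch happened before any integration
        flat = single_lif_flat(component_dir, v_init=-50.05)
        exp = Experiment(
            "", 0.02, 0.1,
            inputs=[InputDriver("constant_current", "N", "I_Syn", value=5.0)],
            logs=[LogRequest("vm", "N", "v"), LogRequest("s", "N", "spike")])
        logs = simulate(flat, exp)
        t_spike = logs.frames["s"]["t_ms"].iloc[0]
        vm = logs.frames["vm"]
        during = vm[(vm["t_ms"] >= t_spike) & (vm["t_ms"] < t_spike + 5.0)]
        assert np.all(during["value"] == -60.0)

    def test_identical_seeds_bitwise_identical_logs(self, component_dir):
        flat = single_lif_flat(component_dir, v_init=-55.0)
        exp = Experiment(
            "", 0.2, 0.1,
            inputs=[InputDriver("constant_current", "N", "I_Syn", value=1.0)],
            logs=[LogRequest("vm", "N", "v")])
        a = simulate(flat, exp, seed=9)
        b = simulate(single_lif_flat(component_dir, v_init=-55.0), exp, seed=9)
        assert a.frames["vm"].equals(b.frames["vm"])

    def test_poisson_driver_deterministic_per_seed(self, component_dir):
        flat = wu_psc_chain(component_dir, w=1.0, tau_syn=1e12)
        exp = Experiment(
            "", 0.5, 0.1,
            inputs=[InputDriver("poisson_spike_source", "wu", "spike_in",
                                rate_hz=100.0)],
            logs=[LogRequest("i", "psc", "I_Syn")])
        a = simulate(flat, exp, seed=5)
        b = simulate(wu_psc_chain(component_dir, w=1.0, tau_syn=1e12),
                     exp, seed=5)
        c = simulate(wu_psc_chain(component_dir, w=1.0, tau_syn=1e12),
                     exp, seed=6)
        assert a.frames["i"].equals(b.frames["i"])
        assert not a.frames["i"].equals(c.frames["i"])

    def test_step_count_exact(self, component_dir):
        flat = single_lif_flat(component_dir)
        exp = Experiment("", 0.0105, 0.1, logs=[LogRequest("vm", "N", "v")])
        logs = simulate(flat, exp)
        assert len(logs.frames["vm"]) == exp.n_steps == 105


class TestGapJunction:
    def test_coupling_currents_antisymmetric(self, component_dir):
        flat = gap_junction_flat(component_dir, v0=-55.0, v1=-65.0, g=0.1)
        exp = Experiment("", 0.05, 0.1,
                         logs=[LogRequest("a", "gj", "I_pre"),
                               LogRequest("b", "gj", "I_post")])
        logs = simulate(flat, exp)
        ia = logs.frames["a"]["value"].to_numpy()
        ib = logs.frames["b"]["value"].to_numpy()
        assert np.allclose(ia, -ib)
        assert ia[0] == pytest.approx(0.1 * (-65.0 + 55.0))

    def test_currents_vanish_at_equal_potentials(self, component_dir):
        flat = gap_junction_flat(component_dir, v0=-58.0, v1=-58.0, g=0.1)
        exp = Experiment("", 0.05, 0.1,
                         logs=[LogRequest("a", "gj", "I_pre"),
                               LogRequest("b", "gj", "I_post")])
        logs = simulate(flat, exp)
        assert np.all(logs.frames["a"]["value"] == 0.0)
        assert np.all(logs.frames["b"]["value"] == 0.0)


class TestLogFormats:
    def test_csv_headers(self, component_dir, tmp_path):
        flat = single_lif_flat(component_dir, v_init=-50.5)
        exp = Experiment(
            "", 0.05, 0.1,
            inputs=[InputDriver("constant_current", "N", "I_Syn", value=2.0)],
            logs=[LogRequest("vm", "N", "v"), LogRequest("s", "N", "spike")])
        logs = simulate(flat, exp)
        logs.write(tmp_path)
        assert (tmp_path / "vm.csv").read_text().splitlines()[0] == \
            "t_ms,index,value"
        assert (tmp_path / "s.csv").read_text().splitlines()[0] == "t_ms,index"

    def test_records_time_sorted(self, component_dir):
        flat = single_lif_flat(component_dir, size=3, v_init=-50.5)
        exp = Experiment(
            "", 0.1, 0.1,
            inputs=[InputDriver("constant_current", "N", "I_Syn", value=2.0)],
            logs=[LogRequest("s", "N", "spike")])
        logs = simulate(flat, exp)
        t = logs.frames["s"]["t_ms"].to_numpy()
        assert np.all(np.diff(t) >= 0)
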