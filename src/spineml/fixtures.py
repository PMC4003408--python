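"""Worked-example components, the Vogels–Abbott benchmark, spike statistics.

Builders return fully validated ComponentClass objects for the standard
leaky integrate-and-fire neuron with refractory period, a fixed-weight
update (spike in, weight impulse out), an exponentially decaying
post-synaptic current, and a gap junction coupling two membrane
potentials.  :func:`build_vogels_abbott` writes a complete three-layer
model (components + network + experiment) of the classic sparse
excitatory/inhibitory benchmark network to disk.

Unit conventions: voltages mV, times ms, currents nA, capacitance nF,
conductance uS — so (I/c_m) and g*(v2-v1)/c_m both land in mV/ms.

The default benchmark parameters follow the current-based (CUBA) variant
of the benchmark as commonly circulated (sparse 4000-neuron network, 80 %
excitatory, 2 % connectivity, suprathreshold leak reversal so activity is
self-sustaining).  They are configuration, not normative values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .component import (Alias, ComponentClass, OnCondition, OnEvent, OnImpulse,
                        Parameter, Port, Regime, StateVariable, write_component)
from .experiment import Experiment, LogRequest, write_experiment
from .expr import parse_expression as pe
from .network import (ComponentInstanceSet, ConnectivitySpec, FixedValue,
                      NetworkModel, Population, PostSynapseRef, Projection,
                      PropertySpec, Synapse, UniformDistribution,
                      WeightUpdateRef, write_network)

__all__ = [
    "make_lif_component",
    "make_fixed_weight_component",
    "make_exp_psc_component",
    "make_gap_junction_component",
    "BenchmarkSpec",
    "build_vogels_abbott",
    "SpikeStats",
    "spike_stats",
]


# ---------------------------------------------------------------------------
# Component builders


def make_lif_component() -> ComponentClass:
    """Leaky integrate-and-fire neuron body with an absolute refractory period.

    Two regimes: ``integrating`` (initial) evolves
    dv/dt = (I_Syn + i_offset)/c_m + (v_rest - v)/tau_m and on v > v_thresh
    resets v, records the spike time and emits a spike event; ``refractory``
    holds every state variable constant until t exceeds
    refractory_end = t_spike + tau_refractory.
    """
    return ComponentClass(
        name="LIF",
        type="neuron_body",
        parameters=[
            Parameter("v_rest", "mV"),
            Parameter("v_thresh", "mV"),
            Parameter("v_reset", "mV"),
            Parameter("tau_m", "ms"),
            Parameter("c_m", "nF"),
            Parameter("tau_refractory", "ms"),
            Parameter("i_offset", "nA"),
        ],
        state_variables=[StateVariable("v", "mV"), StateVariable("t_spike", "ms")],
        aliases=[Alias("refractory_end", pe("t_spike + tau_refractory"), "ms")],
        ports=[
            Port("I_Syn", "receive", "analog", reduce_op="sum", dimension="nA"),
            Port("spike", "send", "event"),
            Port("v", "send", "analog", dimension="mV"),
        ],
        regimes=[
            Regime(
                "integrating",
                time_derivatives=(
                    ("v", pe("(I_Syn + i_offset)/c_m + (v_rest - v)/tau_m")),
                ),
                on_conditions=(
                    OnCondition(
                        trigger=pe("v > v_thresh"),
                        target_regime="refractory",
                        state_assignments=(("v", pe("v_reset")),
                                           ("t_spike", pe("t"))),
                        event_outputs=("spike",),
                    ),
                ),
            ),
            Regime(
                "refractory",
                on_conditions=(
                    OnCondition(trigger=pe("t > refractory_end"),
                                target_regime="integrating"),
                ),
            ),
        ],
        initial_regime="integrating",
    )


def make_fixed_weight_component() -> ComponentClass:
    """Static synapse: each incoming spike emits an impulse of the weight w."""
    return ComponentClass(
        name="FixedWeight",
        type="weight_update",
        parameters=[Parameter("w", "nA")],
        ports=[
            Port("spike_in", "receive", "event"),
            Port("out", "send", "impulse", dimension="nA"),
        ],
        regimes=[
            Regime(
                "on",
                on_events=(
                    OnEvent(source_port="spike_in", target_regime="on",
                            impulse_outputs=(("out", pe("w")),)),
                ),
            ),
        ],
        initial_regime="on",
    )


def make_exp_psc_component() -> ComponentClass:
    """Exponentially decaying post-synaptic current.

    dI_Syn/dt = -I_Syn/tau_syn; each incoming impulse increases I_Syn by
    the carried value.
    """
    return ComponentClass(
        name="ExpPSC",
        type="postsynapse",
        parameters=[Parameter("tau_syn", "ms")],
        state_variables=[StateVariable("I_Syn", "nA")],
        ports=[
            Port("impulse_in", "receive", "impulse", dimension="nA"),
            Port("I_Syn", "send", "analog", dimension="nA"),
        ],
        regimes=[
            Regime(
                "decay",
                time_derivatives=(("I_Syn", pe("-I_Syn/tau_syn")),),
                on_impulses=(
                    OnImpulse(
                        source_port="impulse_in", target_regime="decay",
                        state_assignments=(
                            ("I_Syn", pe("I_Syn + impulse_value")),),
                    ),
                ),
            ),
        ],
        initial_regime="decay",
    )


def make_gap_junction_component() -> ComponentClass:
    """Electrical coupling: I_pre = g*(v_post - v_pre) and its mirror image.

    Both coupling currents are aliases exposed on analogue send ports; the
    two membrane potentials arrive on plain analogue receive ports.
    """
    return ComponentClass(
        name="GapJunction",
        type="generic",
        parameters=[Parameter("g", "uS")],
        aliases=[
            Alias("I_pre", pe("g*(v_post - v_pre)"), "nA"),
            Alias("I_post", pe("g*(v_pre - v_post)"), "nA"),
        ],
        ports=[
            Port("v_pre", "receive", "analog", dimension="mV"),
            Port("v_post", "receive", "analog", dimension="mV"),
            Port("I_pre", "send", "analog", dimension="nA"),
            Port("I_post", "send", "analog", dimension="nA"),
        ],
        regimes=[Regime("coupling")],
        initial_regime="coupling",
    )


# ---------------------------------------------------------------------------
# Benchmark


@dataclass
class BenchmarkSpec:
    """Configuration of the sparse excitatory/inhibitory benchmark network.

    Defaults give the 4000-neuron, 2 %-connectivity current-based variant;
    weights are current impulses in nA, the initial membrane potential is
    uniform between reset and threshold, and the leak reversal sits just
    above threshold so the network is self-sustaining without inputs.
    """

    n_total: int = 4000
    exc_fraction: float = 0.8
    connect_probability: float = 0.02
    weight_exc_na: float = 0.081
    weight_inh_na: float = -0.45
    delay_ms: float = 0.1
    v_rest: float = -49.0
    v_thresh: float = -50.0
    v_reset: float = -60.0
    tau_m: float = 20.0
    c_m: float = 1.0
    tau_refractory: float = 5.0
    tau_syn_exc: float = 5.0
    tau_syn_inh: float = 10.0
    init_v_min: float = -60.0
    init_v_max: float = -50.0
    seed: int = 1234

    def __post_init__(self):
        if not (0.0 < self.exc_fraction < 1.0):
            raise ValueError("exc_fraction must be in (0,1)")
        if not (0.0 <= self.connect_probability <= 1.0):
            raise ValueError("connect_probability must be in [0,1]")

    @property
    def n_exc(self) -> int:
        return round(self.n_total * self.exc_fraction)

    @property
    def n_inh(self) -> int:
        return self.n_total - self.n_exc


def _lif_properties(spec: BenchmarkSpec, v_seed: int) -> list[PropertySpec]:
    return [
        PropertySpec("v_rest", FixedValue(spec.v_rest)),
        PropertySpec("v_thresh", FixedValue(spec.v_thresh)),
        PropertySpec("v_reset", FixedValue(spec.v_reset)),
        PropertySpec("tau_m", FixedValue(spec.tau_m)),
        PropertySpec("c_m", FixedValue(spec.c_m)),
        PropertySpec("tau_refractory", FixedValue(spec.tau_refractory)),
        PropertySpec("v", UniformDistribution(spec.init_v_min, spec.init_v_max,
                                              seed=v_seed)),
    ]


def make_benchmark_network(spec: BenchmarkSpec) -> NetworkModel:
    """The benchmark network model (in memory; components by URL)."""
    pops = {"Excitatory": spec.n_exc, "Inhibitory": spec.n_inh}
    model = NetworkModel()
    seed = spec.seed % (2**31)
    populations = {}
    for i, (name, size) in enumerate(pops.items()):
        populations[name] = Population(
            neuron=ComponentInstanceSet(
                name=name, url="LIF.xml", size=size,
                properties=_lif_properties(spec, (seed + 17 * i + 1) % (2**31))),
        )
    k = 0
    for src in pops:
        excitatory = src == "Excitatory"
        w = spec.weight_exc_na if excitatory else spec.weight_inh_na
        tau = spec.tau_syn_exc if excitatory else spec.tau_syn_inh
        for dst in pops:
            k += 1
            conn = ConnectivitySpec(
                "fixed_probability", probability=spec.connect_probability,
                delay_ms=spec.delay_ms, seed=(seed + 1000 + k) % (2**31))
            wu = WeightUpdateRef(
                instances=ComponentInstanceSet(
                    name=f"{src}_{dst}_wu", url="FixedWeight.xml",
                    properties=[PropertySpec("w", FixedValue(w))]),
                input_src_port="spike", input_dst_port="spike_in")
            ps = PostSynapseRef(
                instances=ComponentInstanceSet(
                    name=f"{src}_{dst}_psc", url="ExpPSC.xml",
                    properties=[PropertySpec("tau_syn", FixedValue(tau))]),
                input_src_port="out", input_dst_port="impulse_in",
                output_src_port="I_Syn", output_dst_port="I_Syn")
            populations[src].projections.append(
                Projection(dst_population=dst,
                           synapses=[Synapse(conn, wu, ps)]))
    model.populations = list(populations.values())
    return model


def make_benchmark_experiment(duration_s: float = 1.0, dt_ms: float = 0.1,
                              integrator: str = "forward_euler") -> Experiment:
    return Experiment(
        model_url="model.xml", duration_s=duration_s, dt_ms=dt_ms,
        integrator=integrator,
        logs=[
            LogRequest("exc_spikes", "Excitatory", "spike"),
            LogRequest("inh_spikes", "Inhibitory", "spike"),
        ],
    )


def build_vogels_abbott(spec: BenchmarkSpec, outdir,
                        duration_s: float = 1.0, dt_ms: float = 0.1) -> dict:
    """Write the complete three-layer benchmark model to ``outdir``.

    Returns the paths of the files written: three component files, the
    network file and the experiment file.  The generated set validates,
    resolves and elaborates cleanly and round-trips through the readers.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for comp in (make_lif_component(), make_fixed_weight_component(),
                 make_exp_psc_component()):
        p = os.path.join(outdir, f"{comp.name}.xml")
        write_component(comp, p)
        paths[comp.name] = p
    paths["network"] = os.path.join(outdir, "model.xml")
    write_network(make_benchmark_network(spec), paths["network"])
    paths["experiment"] = os.path.join(outdir, "experiment.xml")
    write_experiment(make_benchmark_experiment(duration_s, dt_ms),
                     paths["experiment"])
    return paths


# ---------------------------------------------------------------------------
# Spike-train statistics


@dataclass
class SpikeStats:
    """Per-instance inter-spike-interval statistics of one event log.

    ``per_instance`` has one row per instance that spiked at least once:
    columns instance, n_spikes, rate_hz, cv_isi (NaN when fewer than two
    spikes).  ``pooled_isis_ms`` concatenates every instance's ISIs.
    ``n_cv_excluded`` counts instances with under two spikes, for which the
    CV is undefined.
    """

    per_instance: pd.DataFrame
    pooled_isis_ms: np.ndarray
    n_instances: int
    n_cv_excluded: int

    @property
    def mean_rate_hz(self) -> float:
        return float(self.per_instance["rate_hz"].mean()) if self.n_instances else 0.0

    @property
    def mean_cv(self) -> float:
        cv = self.per_instance["cv_isi"].dropna()
        return float(cv.mean()) if len(cv) else float("nan")

    def write_csv(self, path) -> None:
        self.per_instance.to_csv(path, index=False)


def spike_stats(event_log: pd.DataFrame, duration_ms: float,
                discard_initial_ms: float = 0.0) -> SpikeStats:
    """ISI, CV-of-ISI and mean-rate statistics from an event log.

    The log must be time-sorted with columns (t_ms, index).  Spikes before
    ``discard_initial_ms`` are dropped (equilibration discard); rates use
    the remaining effective duration.  CV = std(ISI)/mean(ISI) per
    instance; instances with fewer than two retained spikes are excluded
    from the CV and counted in ``n_cv_excluded``.
    """
    effective_ms = duration_ms - discard_initial_ms
    if effective_ms <= 0:
        raise ValueError("discard exceeds duration")
    if len(event_log) == 0:
        return SpikeStats(
            pd.DataFrame(columns=["instance", "n_spikes", "rate_hz", "cv_isi"]),
            np.empty(0), 0, 0)
    df = event_log[event_log["t_ms"] >= discard_initial_ms]
    rows = []
    pooled = []
    n_excluded = 0
    for inst, grp in df.groupby("index"):
        times = np.sort(grp["t_ms"].to_numpy())
        n = times.size
        if n == 0:
            continue
        rate = n / (effective_ms / 1000.0)
        if n >= 2:
            isis = np.diff(times)
            pooled.append(isis)
            cv = float(np.std(isis) / np.mean(isis)) if np.mean(isis) > 0 else 0.0
        else:
            cv = float("nan")
            n_excluded += 1
        rows.append((int(inst), int(n), rate, cv))
    per_instance = pd.DataFrame(rows,
                                columns=["instance", "n_spikes", "rate_hz",
                                         "cv_isi"])
    pooled_arr = np.concatenate(pooled) if pooled else np.empty(0)
    return SpikeStats(per_instance, pooled_arr, len(rows), n_excluded)
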