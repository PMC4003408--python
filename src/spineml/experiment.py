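"""Experiment layer: simulation settings, external inputs and log outputs.

Time conventions are fixed as: simulation duration in seconds, integration
step dt in milliseconds, spike times and schedules in milliseconds.

XML dialect:

    Experiment
      Model (network_layer attr)
      Simulation (duration_s, dt_ms, integrator, optional simulator attr
                  which is parsed and ignored by this reference engine)
      ConstantInput | TimeVaryingInput | PoissonSpikeInput | SpikeListInput
      LogOutput (name, target, port, optional indices="0,1,...")
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lxml import etree

from .diagnostics import Diagnostic, ModelError
from .network import FlatModel

__all__ = [
    "Experiment",
    "InputDriver",
    "LogRequest",
    "read_experiment",
    "write_experiment",
    "validate_experiment",
]

INTEGRATORS = ("forward_euler", "rk4")
INPUT_KINDS = ("constant_current", "time_varying_current",
               "poisson_spike_source", "explicit_spike_source")


@dataclass
class InputDriver:
    """External drive applied to every instance of a target component set.

    kind:
      constant_current      ``value`` added to an analog receive port each step
      time_varying_current  piecewise-constant ``schedule`` [(time_ms, value)]
      poisson_spike_source  independent Poisson events at ``rate_hz`` per instance
      explicit_spike_source ``spike_times_ms`` delivered to every instance

    For the spike kinds, ``value`` is used as the carried amplitude when the
    target port is an impulse receive port (event ports carry nothing).
    """

    kind: str
    target: str
    port: str
    value: float = 0.0
    schedule: tuple[tuple[float, float], ...] = ()
    rate_hz: float = 0.0
    spike_times_ms: tuple[float, ...] = ()
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in INPUT_KINDS:
            raise ModelError("unknown input kind",
                             [Diagnostic("unknown-input", self.target,
                                         f"kind {self.kind!r}")])
        if self.rate_hz < 0:
            raise ModelError("negative rate",
                             [Diagnostic("bad-rate", self.target,
                                         "rate must be >= 0")])


@dataclass
class LogRequest:
    """Request to record one port of one component set.

    ``indices`` restricts recording to the listed instances (None = all);
    ``mode`` is filled in by :func:`validate_experiment` ('analog'/'event').
    """

    name: str
    target: str
    port: str
    indices: tuple[int, ...] | None = None
    mode: str | None = None


@dataclass
class Experiment:
    model_url: str
    duration_s: float
    dt_ms: float
    integrator: str = "forward_euler"
    inputs: list[InputDriver] = field(default_factory=list)
    logs: list[LogRequest] = field(default_factory=list)
    simulator: str | None = None  # parsed and ignored by the reference engine

    @property
    def n_steps(self) -> int:
        import math

        # guard the ratio against float noise before taking the ceiling
        return math.ceil(round(self.duration_s * 1000.0 / self.dt_ms, 9))

    def invariant_diagnostics(self) -> list[Diagnostic]:
        out = []
        if self.duration_s <= 0:
            out.append(Diagnostic("bad-duration", "Simulation",
                                  "duration must be > 0"))
        if self.dt_ms <= 0:
            out.append(Diagnostic("bad-dt", "Simulation", "dt must be > 0"))
        elif self.duration_s > 0 and self.duration_s * 1000.0 / self.dt_ms < 1:
            out.append(Diagnostic("bad-steps", "Simulation",
                                  "duration/dt must be >= 1"))
        if self.integrator not in INTEGRATORS:
            out.append(Diagnostic("unknown-integrator", "Simulation",
                                  f"integrator {self.integrator!r} not one of "
                                  f"{INTEGRATORS}"))
        names = [l.name for l in self.logs]
        if len(set(names)) != len(names):
            out.append(Diagnostic("duplicate-log-name", "LogOutput",
                                  "log names must be unique"))
        return out


_INPUT_TAGS = {
    "ConstantInput": "constant_current",
    "TimeVaryingInput": "time_varying_current",
    "PoissonSpikeInput": "poisson_spike_source",
    "SpikeListInput": "explicit_spike_source",
}
_KIND_TAGS = {v: k for k, v in _INPUT_TAGS.items()}


def read_experiment(source) -> Experiment:
    """Read an Experiment; raises on structural or invariant violations."""
    from .component import _parse_source

    root = _parse_source(source)
    if root.tag != "Experiment":
        raise ModelError("bad root", [Diagnostic("schema", root.tag,
                                                 "root must be Experiment")])
    model_elem = root.find("Model")
    sim = root.find("Simulation")
    if model_elem is None or sim is None:
        raise ModelError("missing elements",
                         [Diagnostic("schema", "Experiment",
                                     "Model and Simulation required")])
    exp = Experiment(
        model_url=model_elem.get("network_layer", ""),
        duration_s=float(sim.get("duration_s", "0")),
        dt_ms=float(sim.get("dt_ms", "0")),
        integrator=sim.get("integrator", "forward_euler"),
        simulator=sim.get("simulator"),
    )
    for child in root:
        if child.tag in ("Model", "Simulation"):
            continue
        if child.tag in _INPUT_TAGS:
            kind = _INPUT_TAGS[child.tag]
            seed = child.get("seed")
            drv = InputDriver(
                kind=kind,
                target=child.get("target", ""),
                port=child.get("port", ""),
                value=float(child.get("value", "0")),
                rate_hz=float(child.get("rate_hz", "0")),
                seed=int(seed) if seed is not None else None,
            )
            if kind == "time_varying_current":
                drv.schedule = tuple(
                    (float(p.get("time_ms")), float(p.get("value")))
                    for p in child.findall("TimePoint"))
            if kind == "explicit_spike_source":
                drv.spike_times_ms = tuple(
                    float(s.get("time_ms")) for s in child.findall("Spike"))
            exp.inputs.append(drv)
        elif child.tag == "LogOutput":
            idx = child.get("indices")
            exp.logs.append(LogRequest(
                name=child.get("name", ""),
                target=child.get("target", ""),
                port=child.get("port", ""),
                indices=tuple(int(i) for i in idx.split(",")) if idx else None,
            ))
        else:
            raise ModelError("unknown element",
                             [Diagnostic("schema", child.tag,
                                         "unknown experiment-layer element")])
    diags = exp.invariant_diagnostics()
    if diags:
        raise ModelError("invalid experiment", diags)
    return exp


def write_experiment(exp: Experiment, path=None) -> str:
    root = etree.Element("Experiment")
    etree.SubElement(root, "Model", network_layer=exp.model_url)
    sim = etree.SubElement(root, "Simulation", duration_s=repr(exp.duration_s),
                           dt_ms=repr(exp.dt_ms), integrator=exp.integrator)
    if exp.simulator is not None:
        sim.set("simulator", exp.simulator)
    for drv in exp.inputs:
        e = etree.SubElement(root, _KIND_TAGS[drv.kind],
                             target=drv.target, port=drv.port)
        if drv.kind in ("constant_current",):
            e.set("value", repr(drv.value))
        if drv.kind in ("poisson_spike_source", "explicit_spike_source") \
                and drv.value:
            e.set("value", repr(drv.value))
        if drv.kind == "poisson_spike_source":
            e.set("rate_hz", repr(drv.rate_hz))
        if drv.seed is not None:
            e.set("seed", str(drv.seed))
        for t, v in drv.schedule:
            etree.SubElement(e, "TimePoint", time_ms=repr(t), value=repr(v))
        for t in drv.spike_times_ms:
            etree.SubElement(e, "Spike", time_ms=repr(t))
    for log in exp.logs:
        e = etree.SubElement(root, "LogOutput", name=log.name,
                             target=log.target, port=log.port)
        if log.indices is not None:
            e.set("indices", ",".join(str(i) for i in log.indices))
    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def validate_experiment(exp: Experiment, flat: FlatModel) -> list[Diagnostic]:
    """Resolve every input/log target and port against the elaborated model.

    Side effect: fills in each LogRequest's ``mode`` ('event' for event and
    impulse send ports, 'analog' otherwise) so the engine knows whether to
    record event times or values.
    """
    diags = exp.invariant_diagnostics()

    for i, drv in enumerate(exp.inputs):
        tag = f"Input[{i}:{drv.target}/{drv.port}]"
        iset = flat.sets.get(drv.target)
        if iset is None:
            diags.append(Diagnostic("unknown-target", tag,
                                    f"no component set {drv.target!r}"))
            continue
        try:
            port = iset.component.port(drv.port)
        except KeyError:
            diags.append(Diagnostic("unknown-port", tag,
                                    f"no port {drv.port!r} on {drv.target!r}"))
            continue
        if port.direction != "receive":
            diags.append(Diagnostic("direction-mismatch", tag,
                                    "inputs must target receive ports"))
            continue
        if drv.kind in ("constant_current", "time_varying_current"):
            if port.mode != "analog":
                diags.append(Diagnostic("mode-mismatch", tag,
                                        "current inputs need an analog port"))
        else:
            if port.mode not in ("event", "impulse"):
                diags.append(Diagnostic("mode-mismatch", tag,
                                        "spike inputs need an event or "
                                        "impulse port"))

    for log in exp.logs:
        tag = f"LogOutput[{log.name}]"
        iset = flat.sets.get(log.target)
        if iset is None:
            diags.append(Diagnostic("unknown-target", tag,
                                    f"no component set {log.target!r}"))
            continue
        try:
            port = iset.component.port(log.port)
        except KeyError:
            diags.append(Diagnostic("unknown-port", tag,
                                    f"no port {log.port!r} on {log.target!r}"))
            continue
        log.mode = "event" if port.mode in ("event", "impulse") else "analog"
        if port.mode == "analog" and port.direction == "receive" \
                and port.reduce_op is None:
            # readable but unusual; values mirror the bound send port
            pass
        if log.indices is not None and any(
                i < 0 or i >= iset.size for i in log.indices):
            diags.append(Diagnostic("log-index-range", tag,
                                    "logged instance index out of range"))
    return diags
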