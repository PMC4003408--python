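"""Component layer: declarative dynamical units (ComponentClass).

A ComponentClass describes a neuron body, weight update, post-synapse or
generic process as parameters, state variables, aliases, communication
ports and regimes.  Each regime holds a set of time derivatives (ODEs in
the regime's mode of behaviour) plus transitions fired by boolean triggers
(OnCondition), incoming events (OnEvent) or incoming impulses (OnImpulse).
Exactly one regime is the initial regime.

The XML dialect read and written here uses one element per concept:

    ComponentClass > [Parameter | AnalogSendPort | AnalogReceivePort |
                      AnalogReducePort | EventSendPort | EventReceivePort |
                      ImpulseSendPort | ImpulseReceivePort | Dynamics]
    Dynamics (initial_regime attr) > [Regime | StateVariable | Alias]
    Regime > [TimeDerivative | OnCondition | OnEvent | OnImpulse]

All mathematical text lives in MathInline children; the XML reader decodes
entity escapes (&gt; etc.) before parsing.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable

from lxml import etree

from .diagnostics import Diagnostic, ModelError
from .expr import ExpressionTree, free_symbols, has_boolean_ops, parse_expression, serialize

__all__ = [
    "SI_UNITS",
    "Parameter",
    "StateVariable",
    "Alias",
    "Port",
    "OnCondition",
    "OnEvent",
    "OnImpulse",
    "Regime",
    "ComponentClass",
    "read_component",
    "write_component",
    "validate_component",
]

# Supported SI dimension strings.  "none" marks a dimensionless quantity.
SI_UNITS = frozenset(
    {
        "V", "mV", "uV",
        "A", "mA", "uA", "nA", "pA",
        "S", "mS", "uS", "nS",
        "F", "uF", "nF", "pF",
        "s", "ms", "us",
        "Hz",
        "none",
    }
)

# The simulation clock is implicitly bound in every expression context.
RESERVED_SYMBOLS = frozenset({"t"})


@dataclass(frozen=True)
class Parameter:
    """Read-only per-instance constant, e.g. tau_m with dimension ms."""

    name: str
    dimension: str = "none"


@dataclass(frozen=True)
class StateVariable:
    """Mutable per-instance quantity advanced by time derivatives."""

    name: str
    dimension: str = "none"


@dataclass(frozen=True)
class Alias:
    """Named expression over parameters, state variables and other aliases."""

    name: str
    expression: ExpressionTree
    dimension: str = "none"


@dataclass(frozen=True)
class Port:
    """Communication hook: direction send/receive, mode analog/event/impulse.

    ``reduce_op`` is allowed only on analog receive ports and marks a reduce
    port: values arriving from many sources are combined (summed) into one.
    An analog *send* port exposes the state variable or alias of the same
    name.  Impulse ports carry a value with each event; event ports do not.
    """

    name: str
    direction: str  # 'send' | 'receive'
    mode: str  # 'analog' | 'event' | 'impulse'
    reduce_op: str | None = None  # only 'sum'
    dimension: str = "none"


@dataclass(frozen=True)
class OnCondition:
    trigger: ExpressionTree
    target_regime: str
    state_assignments: tuple[tuple[str, ExpressionTree], ...] = ()
    event_outputs: tuple[str, ...] = ()
    impulse_outputs: tuple[tuple[str, ExpressionTree], ...] = ()


@dataclass(frozen=True)
class OnEvent:
    source_port: str
    target_regime: str
    state_assignments: tuple[tuple[str, ExpressionTree], ...] = ()
    event_outputs: tuple[str, ...] = ()
    impulse_outputs: tuple[tuple[str, ExpressionTree], ...] = ()


@dataclass(frozen=True)
class OnImpulse:
    """Impulse handler; the carried value is bound to ``value_symbol``."""

    source_port: str
    target_regime: str
    value_symbol: str = "impulse_value"
    state_assignments: tuple[tuple[str, ExpressionTree], ...] = ()
    event_outputs: tuple[str, ...] = ()
    impulse_outputs: tuple[tuple[str, ExpressionTree], ...] = ()


@dataclass(frozen=True)
class Regime:
    name: str
    time_derivatives: tuple[tuple[str, ExpressionTree], ...] = ()
    on_conditions: tuple[OnCondition, ...] = ()
    on_events: tuple[OnEvent, ...] = ()
    on_impulses: tuple[OnImpulse, ...] = ()


@dataclass
class ComponentClass:
    name: str
    parameters: list[Parameter] = field(default_factory=list)
    state_variables: list[StateVariable] = field(default_factory=list)
    aliases: list[Alias] = field(default_factory=list)
    ports: list[Port] = field(default_factory=list)
    regimes: list[Regime] = field(default_factory=list)
    initial_regime: str = ""
    # Where the network layer instantiates the class; informative only.
    type: str = "generic"  # neuron_body | weight_update | postsynapse | generic

    def regime(self, name: str) -> Regime:
        for r in self.regimes:
            if r.name == name:
                return r
        raise KeyError(name)

    def port(self, name: str) -> Port:
        for p in self.ports:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def symbol_dimensions(self) -> dict[str, str]:
        d = {p.name: p.dimension for p in self.parameters}
        d.update({s.name: s.dimension for s in self.state_variables})
        d.update({a.name: a.dimension for a in self.aliases})
        return d

    def structurally_equal(self, other: "ComponentClass") -> bool:
        return (
            self.name == other.name
            and self.parameters == other.parameters
            and self.state_variables == other.state_variables
            and [(a.name, a.dimension, a.expression.root) for a in self.aliases]
            == [(a.name, a.dimension, a.expression.root) for a in other.aliases]
            and self.ports == other.ports
            and _regimes_key(self.regimes) == _regimes_key(other.regimes)
            and self.initial_regime == other.initial_regime
        )


def _transition_key(tr):
    items = [
        tuple((v, e.root) for v, e in tr.state_assignments),
        tr.event_outputs,
        tuple((p, e.root) for p, e in tr.impulse_outputs),
        tr.target_regime,
    ]
    if isinstance(tr, OnCondition):
        items.append(("trigger", tr.trigger.root))
    else:
        items.append(("src", tr.source_port))
    return tuple(items)


def _regimes_key(regimes):
    return [
        (
            r.name,
            tuple((v, e.root) for v, e in r.time_derivatives),
            tuple(_transition_key(c) for c in r.on_conditions),
            tuple(_transition_key(c) for c in r.on_events),
            tuple(_transition_key(c) for c in r.on_impulses),
        )
        for r in regimes
    ]


# ---------------------------------------------------------------------------
# XML reading

_PORT_ELEMENTS = {
    "AnalogSendPort": ("send", "analog"),
    "AnalogReceivePort": ("receive", "analog"),
    "AnalogReducePort": ("receive", "analog"),
    "EventSendPort": ("send", "event"),
    "EventReceivePort": ("receive", "event"),
    "ImpulseSendPort": ("send", "impulse"),
    "ImpulseReceivePort": ("receive", "impulse"),
}


def _parse_source(source) -> etree._Element:
    if isinstance(source, etree._Element):
        return source
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        return etree.parse(str(source)).getroot()
    if isinstance(source, bytes):
        return etree.fromstring(source)
    if isinstance(source, str):
        return etree.fromstring(source.encode())
    if hasattr(source, "read"):
        return etree.parse(source).getroot()
    raise TypeError(f"cannot read XML from {type(source).__name__}")


def _schema_error(path: str, message: str) -> ModelError:
    return ModelError(
        "component schema violation",
        [Diagnostic("schema", path, message)],
    )


def _math_inline(elem: etree._Element, path: str) -> ExpressionTree:
    m = elem.find("MathInline")
    if m is None or m.text is None or not m.text.strip():
        raise _schema_error(path, "missing MathInline")
    # lxml has already decoded &gt;/&lt;/&amp; in .text
    return parse_expression(m.text.strip())


def _parse_transition_body(elem, path, cls):
    assigns = []
    events = []
    impulses = []
    for child in elem:
        if child.tag == "StateAssignment":
            var = child.get("variable")
            if var is None:
                raise _schema_error(path, "StateAssignment missing variable attribute")
            assigns.append((var, _math_inline(child, f"{path}/StateAssignment[{var}]")))
        elif child.tag == "EventOut":
            port = child.get("port")
            if port is None:
                raise _schema_error(path, "EventOut missing port attribute")
            events.append(port)
        elif child.tag == "ImpulseOut":
            port = child.get("port")
            if port is None:
                raise _schema_error(path, "ImpulseOut missing port attribute")
            impulses.append((port, _math_inline(child, f"{path}/ImpulseOut[{port}]")))
        elif child.tag in ("Trigger", "MathInline"):
            pass
        else:
            raise _schema_error(path, f"unknown element {child.tag}")
    return tuple(assigns), tuple(events), tuple(impulses)


def _parse_regime(elem: etree._Element, cls_name: str) -> Regime:
    name = elem.get("name")
    if name is None:
        raise _schema_error(f"{cls_name}/Regime", "Regime missing name attribute")
    path = f"{cls_name}/Regime[{name}]"
    derivs = []
    conds = []
    events = []
    impulses = []
    for child in elem:
        if child.tag == "TimeDerivative":
            var = child.get("variable")
            if var is None:
                raise _schema_error(path, "TimeDerivative missing variable attribute")
            derivs.append((var, _math_inline(child, f"{path}/TimeDerivative[{var}]")))
        elif child.tag == "OnCondition":
            target = child.get("target_regime", name)
            trig = child.find("Trigger")
            if trig is None:
                raise _schema_error(f"{path}/OnCondition", "missing Trigger")
            trigger = _math_inline(trig, f"{path}/OnCondition/Trigger")
            a, e, i = _parse_transition_body(child, f"{path}/OnCondition", OnCondition)
            conds.append(OnCondition(trigger, target, a, e, i))
        elif child.tag == "OnEvent":
            target = child.get("target_regime", name)
            src = child.get("src_port")
            if src is None:
                raise _schema_error(f"{path}/OnEvent", "missing src_port attribute")
            a, e, i = _parse_transition_body(child, f"{path}/OnEvent", OnEvent)
            events.append(OnEvent(src, target, a, e, i))
        elif child.tag == "OnImpulse":
            target = child.get("target_regime", name)
            src = child.get("src_port")
            if src is None:
                raise _schema_error(f"{path}/OnImpulse", "missing src_port attribute")
            value_symbol = child.get("value_symbol", "impulse_value")
            a, e, i = _parse_transition_body(child, f"{path}/OnImpulse", OnImpulse)
            impulses.append(OnImpulse(src, target, value_symbol, a, e, i))
        else:
            raise _schema_error(path, f"unknown element {child.tag}")
    return Regime(name, tuple(derivs), tuple(conds), tuple(events), tuple(impulses))


def read_component(source) -> ComponentClass:
    """Read a ComponentClass from a path, string, bytes, file or element.

    Raises :class:`ModelError` with an element path on structural
    violations (missing Dynamics, unknown elements, absent attributes).
    """
    root = _parse_source(source)
    if root.tag != "ComponentClass":
        raise _schema_error(root.tag, "root element must be ComponentClass")
    name = root.get("name")
    if name is None:
        raise _schema_error("ComponentClass", "missing name attribute")

    comp = ComponentClass(name=name, type=root.get("type", "generic"))
    dynamics = None
    for child in root:
        if child.tag == "Parameter":
            comp.parameters.append(
                Parameter(child.get("name", ""), child.get("dimension", "none"))
            )
        elif child.tag in _PORT_ELEMENTS:
            direction, mode = _PORT_ELEMENTS[child.tag]
            reduce_op = None
            if child.tag == "AnalogReducePort":
                reduce_op = child.get("reduce_op", "sum")
            comp.ports.append(
                Port(
                    child.get("name", ""),
                    direction,
                    mode,
                    reduce_op,
                    child.get("dimension", "none"),
                )
            )
        elif child.tag == "Dynamics":
            dynamics = child
        else:
            raise _schema_error(f"{name}/{child.tag}", "unknown element")
    if dynamics is None:
        raise _schema_error(name, "missing Dynamics element")

    comp.initial_regime = dynamics.get("initial_regime", "")
    for child in dynamics:
        if child.tag == "Regime":
            comp.regimes.append(_parse_regime(child, name))
        elif child.tag == "StateVariable":
            comp.state_variables.append(
                StateVariable(child.get("name", ""), child.get("dimension", "none"))
            )
        elif child.tag == "Alias":
            comp.aliases.append(
                Alias(
                    child.get("name", ""),
                    _math_inline(child, f"{name}/Alias"),
                    child.get("dimension", "none"),
                )
            )
        else:
            raise _schema_error(f"{name}/Dynamics/{child.tag}", "unknown element")
    if not comp.initial_regime and len(comp.regimes) == 1:
        comp.initial_regime = comp.regimes[0].name
    return comp


# ---------------------------------------------------------------------------
# Validation


def _alias_cycle(aliases: list[Alias]) -> list[str] | None:
    names = {a.name: a for a in aliases}
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {n: WHITE for n in names}

    def visit(n: str, stack: list[str]) -> list[str] | None:
        colour[n] = GREY
        stack.append(n)
        for dep in free_symbols(names[n].expression):
            if dep in names:
                if colour[dep] == GREY:
                    return stack[stack.index(dep):] + [dep]
                if colour[dep] == WHITE:
                    cyc = visit(dep, stack)
                    if cyc:
                        return cyc
        colour[n] = BLACK
        stack.pop()
        return None

    for n in names:
        if colour[n] == WHITE:
            cyc = visit(n, [])
            if cyc:
                return cyc
    return None


def validate_component(comp: ComponentClass) -> list[Diagnostic]:
    """Check every ComponentClass invariant; returns diagnostics (empty = valid)."""
    out: list[Diagnostic] = []
    cn = comp.name

    def err(rule, element, message):
        out.append(Diagnostic(rule, element, message))

    # unique names among value symbols; ports unique among themselves
    seen: dict[str, str] = {}
    for kind, items in (
        ("parameter", comp.parameters),
        ("state variable", comp.state_variables),
        ("alias", comp.aliases),
    ):
        for item in items:
            if item.name in seen:
                err("duplicate-name", f"{cn}/{item.name}",
                    f"{kind} {item.name!r} clashes with {seen[item.name]}")
            else:
                seen[item.name] = kind

    port_names: set[str] = set()
    state_names = {s.name for s in comp.state_variables}
    alias_names = {a.name for a in comp.aliases}
    for p in comp.ports:
        if p.name in port_names:
            err("duplicate-name", f"{cn}/{p.name}", f"duplicate port {p.name!r}")
        port_names.add(p.name)
        if p.reduce_op is not None:
            if not (p.mode == "analog" and p.direction == "receive"):
                err("reduce-op-placement", f"{cn}/{p.name}",
                    "reduce_op only allowed on analog receive ports")
            elif p.reduce_op != "sum":
                err("unsupported-reduce-op", f"{cn}/{p.name}",
                    f"unsupported reduce operator {p.reduce_op!r}")
        if p.mode == "analog" and p.direction == "send":
            if p.name not in state_names and p.name not in alias_names:
                err("send-port-unbacked", f"{cn}/{p.name}",
                    "analog send port must expose a state variable or alias of the same name")
        elif p.name in seen:
            err("duplicate-name", f"{cn}/{p.name}",
                f"port {p.name!r} clashes with {seen[p.name]}")

    # dimensions
    for nm, dim in {**comp.symbol_dimensions, **{p.name: p.dimension for p in comp.ports}}.items():
        if dim not in SI_UNITS:
            err("unknown-dimension", f"{cn}/{nm}", f"dimension {dim!r} not in SI table")

    # initial regime
    regime_names = [r.name for r in comp.regimes]
    if len(set(regime_names)) != len(regime_names):
        err("duplicate-name", cn, "duplicate regime names")
    if not comp.regimes:
        err("no-regime", cn, "component has no regimes")
    elif comp.initial_regime not in regime_names:
        err("initial-regime", cn,
            f"initial regime {comp.initial_regime!r} is not a declared regime")

    # resolvable symbols: parameters, state vars, aliases, receive ports, t
    resolvable = (
        {p.name for p in comp.parameters}
        | state_names
        | alias_names
        | {p.name for p in comp.ports if p.direction == "receive" and p.mode == "analog"}
        | set(RESERVED_SYMBOLS)
    )

    def check_expr(expr: ExpressionTree, element: str, extra: frozenset[str] = frozenset(),
                   allow_boolean: bool = False):
        for sym in sorted(free_symbols(expr)):
            if sym not in resolvable and sym not in extra:
                err("unresolved-symbol", element,
                    f"symbol {sym!r} in {expr.source_text!r} does not resolve")
        if not allow_boolean and has_boolean_ops(expr):
            err("boolean-in-arithmetic", element,
                f"boolean operator not allowed in {expr.source_text!r}")

    for a in comp.aliases:
        check_expr(a.expression, f"{cn}/Alias[{a.name}]")
    cyc = _alias_cycle(comp.aliases)
    if cyc:
        err("alias-cycle", cn, "alias dependency cycle: " + " -> ".join(cyc))

    def check_transition(tr, path, extra=frozenset()):
        if tr.target_regime not in regime_names:
            err("unknown-regime", path, f"target regime {tr.target_regime!r} undeclared")
        for var, e in tr.state_assignments:
            if var not in state_names:
                err("assign-non-state", path, f"assignment to non-state-variable {var!r}")
            check_expr(e, f"{path}/StateAssignment[{var}]", extra)
        for port in tr.event_outputs:
            if port not in port_names or comp.port(port).mode != "event" \
                    or comp.port(port).direction != "send":
                err("unknown-port", path, f"EventOut names no event send port {port!r}")
        for port, e in tr.impulse_outputs:
            if port not in port_names or comp.port(port).mode != "impulse" \
                    or comp.port(port).direction != "send":
                err("unknown-port", path, f"ImpulseOut names no impulse send port {port!r}")
            check_expr(e, f"{path}/ImpulseOut[{port}]", extra)

    for r in comp.regimes:
        path = f"{cn}/Regime[{r.name}]"
        dvars = [v for v, _ in r.time_derivatives]
        for v in dvars:
            if v not in state_names:
                err("derivative-non-state", path, f"time derivative of non-state {v!r}")
        dup = {v for v in dvars if dvars.count(v) > 1}
        for v in sorted(dup):
            err("duplicate-derivative", path,
                f"state variable {v!r} has multiple time derivatives in one regime")
        for v, e in r.time_derivatives:
            check_expr(e, f"{path}/TimeDerivative[{v}]")
        for c in r.on_conditions:
            check_expr(c.trigger, f"{path}/OnCondition/Trigger", allow_boolean=True)
            check_transition(c, f"{path}/OnCondition")
        for ev in r.on_events:
            if ev.source_port not in port_names or comp.port(ev.source_port).mode != "event" \
                    or comp.port(ev.source_port).direction != "receive":
                err("unknown-port", f"{path}/OnEvent",
                    f"src_port names no event receive port {ev.source_port!r}")
            check_transition(ev, f"{path}/OnEvent")
        for im in r.on_impulses:
            if im.source_port not in port_names or comp.port(im.source_port).mode != "impulse" \
                    or comp.port(im.source_port).direction != "receive":
                err("unknown-port", f"{path}/OnImpulse",
                    f"src_port names no impulse receive port {im.source_port!r}")
            check_transition(im, f"{path}/OnImpulse", extra=frozenset({im.value_symbol}))

    return out


# ---------------------------------------------------------------------------
# XML writing

_PORT_TAGS = {
    ("send", "analog"): "AnalogSendPort",
    ("receive", "analog"): "AnalogReceivePort",
    ("send", "event"): "EventSendPort",
    ("receive", "event"): "EventReceivePort",
    ("send", "impulse"): "ImpulseSendPort",
    ("receive", "impulse"): "ImpulseReceivePort",
}


def _math_elem(parent, expr: ExpressionTree):
    m = etree.SubElement(parent, "MathInline")
    m.text = expr.source_text  # lxml escapes >,< as needed on serialisation


def _write_transition_body(elem, tr):
    for var, e in tr.state_assignments:
        sa = etree.SubElement(elem, "StateAssignment", variable=var)
        _math_elem(sa, e)
    for port in tr.event_outputs:
        etree.SubElement(elem, "EventOut", port=port)
    for port, e in tr.impulse_outputs:
        io_ = etree.SubElement(elem, "ImpulseOut", port=port)
        _math_elem(io_, e)


def write_component(comp: ComponentClass, path=None) -> str:
    """Serialise a validated ComponentClass to XML text (optionally to a file).

    Refuses (raising :class:`ModelError`) if validation finds errors;
    the produced document reads back structurally equal.
    """
    diags = validate_component(comp)
    if diags:
        raise ModelError(f"refusing to write invalid component {comp.name!r}", diags)

    root = etree.Element("ComponentClass", name=comp.name)
    if comp.type != "generic":
        root.set("type", comp.type)
    for p in comp.parameters:
        etree.SubElement(root, "Parameter", name=p.name, dimension=p.dimension)
    for p in comp.ports:
        if p.reduce_op is not None:
            e = etree.SubElement(root, "AnalogReducePort", name=p.name,
                                 dimension=p.dimension)
            e.set("reduce_op", p.reduce_op)
        else:
            e = etree.SubElement(root, _PORT_TAGS[(p.direction, p.mode)],
                                 name=p.name, dimension=p.dimension)
    dyn = etree.SubElement(root, "Dynamics", initial_regime=comp.initial_regime)
    for r in comp.regimes:
        re_ = etree.SubElement(dyn, "Regime", name=r.name)
        for var, e in r.time_derivatives:
            td = etree.SubElement(re_, "TimeDerivative", variable=var)
            _math_elem(td, e)
        for c in r.on_conditions:
            oc = etree.SubElement(re_, "OnCondition", target_regime=c.target_regime)
            trig = etree.SubElement(oc, "Trigger")
            _math_elem(trig, c.trigger)
            _write_transition_body(oc, c)
        for ev in r.on_events:
            oe = etree.SubElement(re_, "OnEvent", src_port=ev.source_port,
                                  target_regime=ev.target_regime)
            _write_transition_body(oe, ev)
        for im in r.on_impulses:
            oi = etree.SubElement(re_, "OnImpulse", src_port=im.source_port,
                                  target_regime=im.target_regime)
            if im.value_symbol != "impulse_value":
                oi.set("value_symbol", im.value_symbol)
            _write_transition_body(oi, im)
    for s in comp.state_variables:
        etree.SubElement(dyn, "StateVariable", name=s.name, dimension=s.dimension)
    for a in comp.aliases:
        al = etree.SubElement(dyn, "Alias", name=a.name, dimension=a.dimension)
        _math_elem(al, a.expression)

    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
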