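"""Network layer: populations, projections, groups and elaboration.

The high-level syntax composes a network from Populations of neuron-body
component instances linked by Projections.  Each Projection holds one or
more Synapses; a Synapse pairs a connectivity pattern with a WeightUpdate
component (one instance per connection) and a PostSynapse component (one
instance per destination neuron).  The low-level extension adds Groups
(component sets that are not neuron bodies) and generic Inputs (direct
port-to-port connections), which is how non-synaptic communication such as
gap junctions is expressed.

Elaboration expands the declarative model into a :class:`FlatModel`: one
array-backed instance set per component set, plus directed, delayed edges
between (instance, port) endpoints.  Instance indices are 0-based
throughout, including ValueList property indices.

Connectivity elements are looked up in a plug-in registry keyed by XML
element name, so dialect extensions (distance-based rules, CSA, ...) can be
registered without touching the reader.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from lxml import etree

from .component import ComponentClass, read_component, validate_component
from .diagnostics import Diagnostic, ModelError

__all__ = [
    "FixedValue",
    "UniformDistribution",
    "NormalDistribution",
    "PoissonDistribution",
    "ValueList",
    "PropertySpec",
    "ConnectivitySpec",
    "ComponentInstanceSet",
    "WeightUpdateRef",
    "PostSynapseRef",
    "Synapse",
    "Projection",
    "Population",
    "Group",
    "GenericInput",
    "NetworkModel",
    "ResolvedModel",
    "InstanceSet",
    "EdgeGroup",
    "FlatModel",
    "read_network",
    "write_network",
    "resolve_references",
    "instantiate_property",
    "build_connectivity",
    "elaborate",
    "register_connectivity",
    "file_loader",
    "read_connection_list_csv",
    "write_connection_list_csv",
]


# ---------------------------------------------------------------------------
# Property value specifications


@dataclass(frozen=True)
class FixedValue:
    value: float


@dataclass(frozen=True)
class UniformDistribution:
    minimum: float
    maximum: float
    seed: int | None = None


@dataclass(frozen=True)
class NormalDistribution:
    """Parameterised by mean and *variance* (not standard deviation)."""

    mean: float
    variance: float
    seed: int | None = None


@dataclass(frozen=True)
class PoissonDistribution:
    """Integer counts drawn with the given mean."""

    mean: float
    seed: int | None = None


@dataclass(frozen=True)
class ValueList:
    """Explicit (index, value) pairs; unlisted indices default to 0."""

    values: tuple[tuple[int, float], ...]


PropertyValue = FixedValue | UniformDistribution | NormalDistribution | \
    PoissonDistribution | ValueList


@dataclass(frozen=True)
class PropertySpec:
    name: str  # parameter or state variable of the referenced component
    value: PropertyValue


# ---------------------------------------------------------------------------
# Connectivity


@dataclass(frozen=True)
class ConnectivitySpec:
    kind: str  # one_to_one | all_to_all | fixed_probability | connection_list
    probability: float | None = None
    explicit_pairs: tuple[tuple[int, int, float], ...] = ()
    delay_ms: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind == "fixed_probability":
            if self.probability is None or not (0.0 <= self.probability <= 1.0):
                raise ValueError(f"probability must be in [0,1], got {self.probability}")
        if self.delay_ms < 0:
            raise ValueError("delay must be >= 0")
        for _, _, d in self.explicit_pairs:
            if d < 0:
                raise ValueError("delay must be >= 0")


_KIND_TO_TAG = {
    "one_to_one": "OneToOneConnection",
    "all_to_all": "AllToAllConnection",
    "fixed_probability": "FixedProbabilityConnection",
    "connection_list": "ConnectionList",
}


def _read_delay(elem) -> float:
    d = elem.find("Delay")
    return float(d.get("value", "0")) if d is not None else 0.0


def _read_one_to_one(elem) -> ConnectivitySpec:
    return ConnectivitySpec("one_to_one", delay_ms=_read_delay(elem))


def _read_all_to_all(elem) -> ConnectivitySpec:
    return ConnectivitySpec("all_to_all", delay_ms=_read_delay(elem))


def _read_fixed_probability(elem) -> ConnectivitySpec:
    seed = elem.get("seed")
    return ConnectivitySpec(
        "fixed_probability",
        probability=float(elem.get("probability", "0")),
        delay_ms=_read_delay(elem),
        seed=int(seed) if seed is not None else None,
    )


def _read_connection_list(elem) -> ConnectivitySpec:
    pairs = []
    for c in elem.findall("Connection"):
        pairs.append((int(c.get("src")), int(c.get("dst")),
                      float(c.get("delay", "0"))))
    return ConnectivitySpec("connection_list", explicit_pairs=tuple(pairs))


def _write_connectivity(spec: ConnectivitySpec, parent) -> None:
    tag = _KIND_TO_TAG[spec.kind]
    e = etree.SubElement(parent, tag)
    if spec.kind == "fixed_probability":
        e.set("probability", repr(spec.probability))
        if spec.seed is not None:
            e.set("seed", str(spec.seed))
    if spec.kind == "connection_list":
        for s, d, dl in spec.explicit_pairs:
            etree.SubElement(e, "Connection", src=str(s), dst=str(d), delay=repr(dl))
    else:
        etree.SubElement(e, "Delay", value=repr(spec.delay_ms))


# plug-in registry: XML element name -> reader(elem) -> ConnectivitySpec
_CONNECTIVITY_READERS: dict[str, Callable] = {
    "OneToOneConnection": _read_one_to_one,
    "AllToAllConnection": _read_all_to_all,
    "FixedProbabilityConnection": _read_fixed_probability,
    "ConnectionList": _read_connection_list,
}


def register_connectivity(element_name: str, reader: Callable) -> None:
    """Register a substitutable connectivity element.

    ``reader(elem)`` must return a :class:`ConnectivitySpec` (typically a
    ``connection_list`` with materialised pairs, mirroring how schema
    substitution groups admit new primitives without reader changes).
    """
    _CONNECTIVITY_READERS[element_name] = reader


def _parse_connectivity(parent, path: str) -> ConnectivitySpec:
    for child in parent:
        if child.tag in _CONNECTIVITY_READERS:
            return _CONNECTIVITY_READERS[child.tag](child)
    for child in parent:
        if child.tag.endswith("Connection") or child.tag.endswith("ConnectionList"):
            raise ModelError(
                "unknown connectivity element",
                [Diagnostic("extension-not-registered", f"{path}/{child.tag}",
                            f"no connectivity plug-in registered for {child.tag!r}")],
            )
    raise ModelError(
        "missing connectivity",
        [Diagnostic("schema", path, "no connectivity element found")],
    )


def build_connectivity(spec: ConnectivitySpec, n_src: int, n_dst: int,
                       rng_seed: int | None = None):
    """Generate connection triples (src, dst, delay_ms) as three arrays.

    fixed_probability includes each ordered (src, dst) pair independently
    with probability p; self-connections are allowed when source and
    destination are the same set.  Deterministic for a fixed seed (the
    spec's own seed wins over ``rng_seed``).
    """
    if n_src < 1 or n_dst < 1:
        raise ValueError("component-set sizes must be >= 1")
    if spec.kind == "one_to_one":
        if n_src != n_dst:
            raise ModelError(
                "one_to_one size mismatch",
                [Diagnostic("one-to-one-size", "OneToOneConnection",
                            f"source size {n_src} != destination size {n_dst}")],
            )
        idx = np.arange(n_src)
        return idx, idx.copy(), np.full(n_src, spec.delay_ms)
    if spec.kind == "all_to_all":
        src = np.repeat(np.arange(n_src), n_dst)
        dst = np.tile(np.arange(n_dst), n_src)
        return src, dst, np.full(n_src * n_dst, spec.delay_ms)
    if spec.kind == "fixed_probability":
        seed = spec.seed if spec.seed is not None else rng_seed
        rng = np.random.default_rng(seed)
        mask = rng.random(n_src * n_dst) < spec.probability
        flat = np.flatnonzero(mask)
        src, dst = np.divmod(flat, n_dst)
        return src, dst, np.full(flat.size, spec.delay_ms)
    if spec.kind == "connection_list":
        if spec.explicit_pairs:
            arr = np.asarray(spec.explicit_pairs, dtype=float)
            return arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2]
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                np.empty(0))
    raise ValueError(f"unknown connectivity kind {spec.kind!r}")


def read_connection_list_csv(path) -> ConnectivitySpec:
    """Import an explicit connection list from CSV (src,dst,delay_ms)."""
    import pandas as pd

    df = pd.read_csv(path)
    pairs = tuple(
        (int(r.src), int(r.dst), float(r.delay_ms)) for r in df.itertuples()
    )
    return ConnectivitySpec("connection_list", explicit_pairs=pairs)


def write_connection_list_csv(spec: ConnectivitySpec, path) -> None:
    import pandas as pd

    pd.DataFrame(
        list(spec.explicit_pairs), columns=["src", "dst", "delay_ms"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Network model


@dataclass
class ComponentInstanceSet:
    """A named set of instances of one ComponentClass located by URL."""

    name: str
    url: str
    size: int | None = None  # None when derived (weight update / post-synapse)
    properties: list[PropertySpec] = field(default_factory=list)


@dataclass
class WeightUpdateRef:
    instances: ComponentInstanceSet
    input_src_port: str  # port on the pre-synaptic neuron
    input_dst_port: str  # port on the weight update
    feedback_src_port: str | None = None  # port on the post-synaptic neuron
    feedback_dst_port: str | None = None


@dataclass
class PostSynapseRef:
    instances: ComponentInstanceSet
    input_src_port: str  # port on the weight update
    input_dst_port: str  # port on the post-synapse
    output_src_port: str  # port on the post-synapse
    output_dst_port: str  # port on the destination neuron


@dataclass
class Synapse:
    connectivity: ConnectivitySpec
    weight_update: WeightUpdateRef
    post_synapse: PostSynapseRef


@dataclass
class Projection:
    dst_population: str
    synapses: list[Synapse] = field(default_factory=list)


@dataclass
class Population:
    neuron: ComponentInstanceSet
    projections: list[Projection] = field(default_factory=list)


@dataclass
class Group:
    """Low-level component set that does not represent neuron bodies."""

    instances: ComponentInstanceSet


@dataclass
class GenericInput:
    """Direct port-to-port connection between two component sets."""

    src: str
    dst: str
    src_port: str
    dst_port: str
    connectivity: ConnectivitySpec


@dataclass
class NetworkModel:
    populations: list[Population] = field(default_factory=list)
    groups: list[Group] = field(default_factory=list)
    inputs: list[GenericInput] = field(default_factory=list)

    def component_sets(self):
        """All (set, role) pairs declared in the model, in document order."""
        out = []
        for pop in self.populations:
            out.append((pop.neuron, "neuron_body"))
            for proj in pop.projections:
                for syn in proj.synapses:
                    out.append((syn.weight_update.instances, "weight_update"))
                    out.append((syn.post_synapse.instances, "postsynapse"))
        for g in self.groups:
            out.append((g.instances, "generic"))
        return out


# ---------------------------------------------------------------------------
# XML reading / writing


def _parse_properties(elem, path: str) -> list[PropertySpec]:
    props = []
    for p in elem.findall("Property"):
        name = p.get("name")
        if name is None:
            raise ModelError("property missing name",
                             [Diagnostic("schema", path, "Property missing name")])
        value = None
        for v in p:
            if v.tag == "FixedValue":
                value = FixedValue(float(v.get("value")))
            elif v.tag == "UniformDistribution":
                s = v.get("seed")
                value = UniformDistribution(float(v.get("minimum")),
                                            float(v.get("maximum")),
                                            int(s) if s else None)
            elif v.tag == "NormalDistribution":
                s = v.get("seed")
                value = NormalDistribution(float(v.get("mean")),
                                           float(v.get("variance")),
                                           int(s) if s else None)
            elif v.tag == "PoissonDistribution":
                s = v.get("seed")
                value = PoissonDistribution(float(v.get("mean")),
                                            int(s) if s else None)
            elif v.tag == "ValueList":
                vals = tuple((int(x.get("index")), float(x.get("value")))
                             for x in v.findall("Value"))
                value = ValueList(vals)
            else:
                raise ModelError(
                    "unknown property value element",
                    [Diagnostic("schema", f"{path}/Property[{name}]",
                                f"unknown element {v.tag}")],
                )
        if value is None:
            raise ModelError("property missing value",
                             [Diagnostic("schema", f"{path}/Property[{name}]",
                                         "no value element")])
        props.append(PropertySpec(name, value))
    return props


def _parse_instance_set(elem, path: str, need_size: bool) -> ComponentInstanceSet:
    name = elem.get("name")
    url = elem.get("url")
    if name is None or url is None:
        raise ModelError("component set missing attributes",
                         [Diagnostic("schema", path, "name and url required")])
    size = elem.get("size")
    if need_size and size is None:
        raise ModelError("missing size",
                         [Diagnostic("schema", f"{path}[{name}]", "size required")])
    return ComponentInstanceSet(
        name=name, url=url,
        size=int(size) if size is not None else None,
        properties=_parse_properties(elem, f"{path}[{name}]"),
    )


def read_network(source) -> NetworkModel:
    """Read a network model (high- plus low-level layers) from XML."""
    from .component import _parse_source

    root = _parse_source(source)
    if root.tag != "SpineML":
        raise ModelError("bad root",
                         [Diagnostic("schema", root.tag,
                                     "root element must be SpineML")])
    model = NetworkModel()
    for child in root:
        if child.tag == "Population":
            neuron_elem = child.find("Neuron")
            if neuron_elem is None:
                raise ModelError("population missing Neuron",
                                 [Diagnostic("schema", "Population",
                                             "Neuron element required")])
            pop = Population(neuron=_parse_instance_set(neuron_elem, "Neuron", True))
            for proj_elem in child.findall("Projection"):
                dst = proj_elem.get("dst_population")
                if dst is None:
                    raise ModelError("projection missing dst_population",
                                     [Diagnostic("schema", "Projection",
                                                 "dst_population required")])
                proj = Projection(dst_population=dst)
                for syn_elem in proj_elem.findall("Synapse"):
                    spath = f"{pop.neuron.name}->{dst}/Synapse"
                    conn = _parse_connectivity(syn_elem, spath)
                    wu_elem = syn_elem.find("WeightUpdate")
                    ps_elem = syn_elem.find("PostSynapse")
                    if wu_elem is None or ps_elem is None:
                        raise ModelError(
                            "synapse missing components",
                            [Diagnostic("schema", spath,
                                        "WeightUpdate and PostSynapse required")])
                    wu = WeightUpdateRef(
                        instances=_parse_instance_set(wu_elem, spath, False),
                        input_src_port=wu_elem.get("input_src_port"),
                        input_dst_port=wu_elem.get("input_dst_port"),
                        feedback_src_port=wu_elem.get("feedback_src_port"),
                        feedback_dst_port=wu_elem.get("feedback_dst_port"),
                    )
                    ps = PostSynapseRef(
                        instances=_parse_instance_set(ps_elem, spath, False),
                        input_src_port=ps_elem.get("input_src_port"),
                        input_dst_port=ps_elem.get("input_dst_port"),
                        output_src_port=ps_elem.get("output_src_port"),
                        output_dst_port=ps_elem.get("output_dst_port"),
                    )
                    proj.synapses.append(Synapse(conn, wu, ps))
                pop.projections.append(proj)
            model.populations.append(pop)
        elif child.tag == "Group":
            model.groups.append(Group(_parse_instance_set(child, "Group", True)))
        elif child.tag == "Input":
            conn = _parse_connectivity(child, "Input")
            model.inputs.append(GenericInput(
                src=child.get("src"), dst=child.get("dst"),
                src_port=child.get("src_port"), dst_port=child.get("dst_port"),
                connectivity=conn,
            ))
        else:
            raise ModelError("unknown element",
                             [Diagnostic("schema", child.tag,
                                         "unknown network-layer element")])
    return model


def _write_properties(elem, props: list[PropertySpec]) -> None:
    for p in props:
        pe = etree.SubElement(elem, "Property", name=p.name)
        v = p.value
        if isinstance(v, FixedValue):
            etree.SubElement(pe, "FixedValue", value=repr(v.value))
        elif isinstance(v, UniformDistribution):
            e = etree.SubElement(pe, "UniformDistribution",
                                 minimum=repr(v.minimum), maximum=repr(v.maximum))
            if v.seed is not None:
                e.set("seed", str(v.seed))
        elif isinstance(v, NormalDistribution):
            e = etree.SubElement(pe, "NormalDistribution",
                                 mean=repr(v.mean), variance=repr(v.variance))
            if v.seed is not None:
                e.set("seed", str(v.seed))
        elif isinstance(v, PoissonDistribution):
            e = etree.SubElement(pe, "PoissonDistribution", mean=repr(v.mean))
            if v.seed is not None:
                e.set("seed", str(v.seed))
        elif isinstance(v, ValueList):
            e = etree.SubElement(pe, "ValueList")
            for idx, val in v.values:
                etree.SubElement(e, "Value", index=str(idx), value=repr(val))


def _write_instance_set(parent, tag: str, s: ComponentInstanceSet, **attrs) -> None:
    e = etree.SubElement(parent, tag, name=s.name, url=s.url)
    if s.size is not None:
        e.set("size", str(s.size))
    for k, v in attrs.items():
        if v is not None:
            e.set(k, v)
    _write_properties(e, s.properties)


def write_network(model: NetworkModel, path=None) -> str:
    """Serialise a NetworkModel to XML text (optionally to a file)."""
    root = etree.Element("SpineML")
    for pop in model.populations:
        pe = etree.SubElement(root, "Population")
        _write_instance_set(pe, "Neuron", pop.neuron)
        for proj in pop.projections:
            pj = etree.SubElement(pe, "Projection", dst_population=proj.dst_population)
            for syn in proj.synapses:
                se = etree.SubElement(pj, "Synapse")
                _write_connectivity(syn.connectivity, se)
                wu = syn.weight_update
                _write_instance_set(
                    se, "WeightUpdate", wu.instances,
                    input_src_port=wu.input_src_port,
                    input_dst_port=wu.input_dst_port,
                    feedback_src_port=wu.feedback_src_port,
                    feedback_dst_port=wu.feedback_dst_port,
                )
                ps = syn.post_synapse
                _write_instance_set(
                    se, "PostSynapse", ps.instances,
                    input_src_port=ps.input_src_port,
                    input_dst_port=ps.input_dst_port,
                    output_src_port=ps.output_src_port,
                    output_dst_port=ps.output_dst_port,
                )
    for g in model.groups:
        _write_instance_set(root, "Group", g.instances)
    for inp in model.inputs:
        ie = etree.SubElement(root, "Input", src=inp.src, dst=inp.dst,
                              src_port=inp.src_port, dst_port=inp.dst_port)
        _write_connectivity(inp.connectivity, ie)
    text = etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Reference resolution


def file_loader(base_dir) -> Callable[[str], ComponentClass]:
    """URL loader resolving component files relative to ``base_dir``."""
    cache: dict[str, ComponentClass] = {}

    def load(url: str) -> ComponentClass:
        if url not in cache:
            cache[url] = read_component(os.path.join(base_dir, url))
        return cache[url]

    return load


@dataclass
class ResolvedModel:
    model: NetworkModel
    components: dict[str, ComponentClass]  # component-set name -> class
    roles: dict[str, str]  # component-set name -> role
    diagnostics: list[Diagnostic]


def resolve_references(model: NetworkModel,
                       loader: Callable[[str], ComponentClass]) -> ResolvedModel:
    """Bind every component-set URL to a validated ComponentClass.

    Checks set-name uniqueness, projection destinations, property names,
    port existence and the mode/direction compatibility of every port
    binding in the synaptic chains and generic inputs.
    """
    diags: list[Diagnostic] = []
    components: dict[str, ComponentClass] = {}
    roles: dict[str, str] = {}

    for inst, role in model.component_sets():
        if inst.name in components:
            diags.append(Diagnostic("duplicate-set-name", inst.name,
                                    f"component set {inst.name!r} declared twice"))
            continue
        try:
            comp = loader(inst.url)
        except Exception as exc:  # missing file, parse failure
            diags.append(Diagnostic("missing-url", inst.name,
                                    f"cannot load {inst.url!r}: {exc}"))
            continue
        cdiags = validate_component(comp)
        if cdiags:
            diags.extend(replace(d, element=f"{inst.name}:{d.element}")
                         for d in cdiags)
            continue
        components[inst.name] = comp
        roles[inst.name] = role
        if inst.size is not None and inst.size < 1:
            diags.append(Diagnostic("bad-size", inst.name, "size must be >= 1"))
        symbols = ({p.name for p in comp.parameters}
                   | {s.name for s in comp.state_variables})
        for prop in inst.properties:
            if prop.name not in symbols:
                diags.append(Diagnostic(
                    "unknown-property", f"{inst.name}/{prop.name}",
                    f"{prop.name!r} is not a parameter or state variable of "
                    f"{comp.name!r}"))
            if isinstance(prop.value, ValueList):
                idxs = [i for i, _ in prop.value.values]
                if len(set(idxs)) != len(idxs):
                    diags.append(Diagnostic("valuelist-duplicate-index",
                                            f"{inst.name}/{prop.name}",
                                            "duplicate indices in ValueList"))
                if inst.size is not None and any(
                        i < 0 or i >= inst.size for i in idxs):
                    diags.append(Diagnostic("valuelist-index-range",
                                            f"{inst.name}/{prop.name}",
                                            "ValueList index out of [0, size)"))
            if isinstance(prop.value, NormalDistribution) and prop.value.variance < 0:
                diags.append(Diagnostic("bad-variance", f"{inst.name}/{prop.name}",
                                        "variance must be >= 0"))

    pop_names = {p.neuron.name for p in model.populations}

    def check_port(set_name: str, port_name: str | None, direction: str,
                   binding: str, modes=("analog", "event", "impulse")):
        """Returns the port mode, or None after emitting a diagnostic."""
        if set_name not in components:
            return None
        if port_name is None:
            diags.append(Diagnostic("missing-port-attribute", binding,
                                    "port attribute absent"))
            return None
        comp = components[set_name]
        try:
            port = comp.port(port_name)
        except KeyError:
            diags.append(Diagnostic("unknown-port", binding,
                                    f"component {comp.name!r} has no port "
                                    f"{port_name!r}"))
            return None
        if port.direction != direction:
            diags.append(Diagnostic("direction-mismatch", binding,
                                    f"port {port_name!r} is a {port.direction} "
                                    f"port; {direction} required"))
            return None
        if port.mode not in modes:
            diags.append(Diagnostic("mode-mismatch", binding,
                                    f"port {port_name!r} has mode {port.mode}"))
            return None
        return port.mode

    def check_pair(src_set, src_port, dst_set, dst_port, binding):
        m1 = check_port(src_set, src_port, "send", binding)
        m2 = check_port(dst_set, dst_port, "receive", binding)
        if m1 and m2 and m1 != m2:
            diags.append(Diagnostic("mode-mismatch", binding,
                                    f"{m1} send port bound to {m2} receive port"))

    for pop in model.populations:
        for proj in pop.projections:
            if proj.dst_population not in pop_names:
                diags.append(Diagnostic(
                    "unknown-population", f"{pop.neuron.name}->{proj.dst_population}",
                    f"projection destination {proj.dst_population!r} not declared"))
                continue
            for k, syn in enumerate(proj.synapses):
                tag = f"{pop.neuron.name}->{proj.dst_population}/Synapse[{k}]"
                wu, ps = syn.weight_update, syn.post_synapse
                check_pair(pop.neuron.name, wu.input_src_port,
                           wu.instances.name, wu.input_dst_port, f"{tag}/WeightUpdate")
                check_pair(wu.instances.name, ps.input_src_port,
                           ps.instances.name, ps.input_dst_port, f"{tag}/PostSynapse")
                check_pair(ps.instances.name, ps.output_src_port,
                           proj.dst_population, ps.output_dst_port,
                           f"{tag}/PostSynapse output")
                if (wu.feedback_src_port is None) != (wu.feedback_dst_port is None):
                    diags.append(Diagnostic("feedback-incomplete",
                                            f"{tag}/WeightUpdate",
                                            "feedback needs both ports"))
                elif wu.feedback_src_port is not None:
                    check_pair(proj.dst_population, wu.feedback_src_port,
                               wu.instances.name, wu.feedback_dst_port,
                               f"{tag}/WeightUpdate feedback")

    set_names = set(components)
    for i, inp in enumerate(model.inputs):
        tag = f"Input[{i}:{inp.src}->{inp.dst}]"
        for nm in (inp.src, inp.dst):
            if nm not in set_names:
                diags.append(Diagnostic("unknown-set", tag,
                                        f"component set {nm!r} not declared"))
        check_pair(inp.src, inp.src_port, inp.dst, inp.dst_port, tag)

    return ResolvedModel(model, components, roles, diags)


# ---------------------------------------------------------------------------
# Property instantiation


def _derived_seed(global_seed: int, *names) -> int:
    h = zlib.crc32("/".join(str(n) for n in names).encode())
    return (int(global_seed) * 2654435761 + h) % (2**31)


def instantiate_property(spec: PropertySpec | PropertyValue, size: int,
                         rng_seed: int | None = None) -> np.ndarray:
    """Materialise one property into a value vector of length ``size``.

    Distribution specs use their own embedded seed when present, otherwise
    ``rng_seed``.  ValueList sets the listed indices and leaves the rest at
    the default 0 (the partial-list rule); a property absent altogether is
    handled by the caller as an all-zero vector.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    value = spec.value if isinstance(spec, PropertySpec) else spec
    if isinstance(value, FixedValue):
        return np.full(size, value.value, dtype=float)
    if isinstance(value, UniformDistribution):
        rng = np.random.default_rng(value.seed if value.seed is not None else rng_seed)
        return rng.uniform(value.minimum, value.maximum, size)
    if isinstance(value, NormalDistribution):
        rng = np.random.default_rng(value.seed if value.seed is not None else rng_seed)
        return rng.normal(value.mean, np.sqrt(value.variance), size)
    if isinstance(value, PoissonDistribution):
        rng = np.random.default_rng(value.seed if value.seed is not None else rng_seed)
        return rng.poisson(value.mean, size).astype(float)
    if isinstance(value, ValueList):
        out = np.zeros(size, dtype=float)
        for idx, val in value.values:
            if idx < 0 or idx >= size:
                raise ModelError(
                    "ValueList index out of range",
                    [Diagnostic("valuelist-index-range", "ValueList",
                                f"index {idx} outside [0, {size})")])
            out[idx] = val
        return out
    raise TypeError(f"unknown property value {value!r}")


# ---------------------------------------------------------------------------
# Elaboration


@dataclass
class InstanceSet:
    """Array-backed instances of one ComponentClass."""

    name: str
    component: ComponentClass
    size: int
    parameters: dict[str, np.ndarray]
    initial_state: dict[str, np.ndarray]


@dataclass
class EdgeGroup:
    """A bundle of same-shaped port bindings between two instance sets.

    ``src_indices[i] -> dst_indices[i]`` with per-pair ``delays_ms[i]``.
    The number of individual bindings the group represents is its length.
    """

    src_set: str
    src_port: str
    dst_set: str
    dst_port: str
    mode: str  # analog | event | impulse
    src_indices: np.ndarray
    dst_indices: np.ndarray
    delays_ms: np.ndarray

    def __len__(self) -> int:
        return int(self.src_indices.size)


@dataclass
class FlatModel:
    sets: dict[str, InstanceSet]
    edges: list[EdgeGroup]

    @property
    def n_edges(self) -> int:
        return sum(len(e) for e in self.edges)

    def edges_into(self, set_name: str, port_name: str):
        return [e for e in self.edges
                if e.dst_set == set_name and e.dst_port == port_name]


def _make_instance_set(inst: ComponentInstanceSet, comp: ComponentClass,
                       size: int, global_seed: int) -> InstanceSet:
    params = {}
    states = {}
    specs = {p.name: p for p in inst.properties}
    for p in comp.parameters:
        if p.name in specs:
            params[p.name] = instantiate_property(
                specs[p.name], size,
                _derived_seed(global_seed, inst.name, p.name))
        else:
            params[p.name] = np.zeros(size)
    for s in comp.state_variables:
        if s.name in specs:
            states[s.name] = instantiate_property(
                specs[s.name], size,
                _derived_seed(global_seed, inst.name, s.name))
        else:
            states[s.name] = np.zeros(size)
    return InstanceSet(inst.name, comp, size, params, states)


def elaborate(resolved: ResolvedModel, seed: int = 0) -> FlatModel:
    """Expand a resolved model into per-instance arrays and port bindings.

    One weight-update instance is created per generated connection and one
    post-synapse instance per destination neuron (per synapse).  Binding
    edges follow the chain pre-neuron -> weight update -> post-synapse ->
    destination neuron, plus optional feedback edges and all generic-input
    edges.  The connectivity delay rides on the pre-neuron -> weight-update
    edge; the other synaptic hops have zero declared delay.

    Deterministic: the same (model, seed) always produces bitwise-identical
    property vectors and edge lists.
    """
    if resolved.diagnostics:
        raise ModelError("cannot elaborate unresolved model", resolved.diagnostics)
    model = resolved.model
    comps = resolved.components
    sets: dict[str, InstanceSet] = {}
    edges: list[EdgeGroup] = []

    pop_sizes = {p.neuron.name: p.neuron.size for p in model.populations}

    for pop in model.populations:
        sets[pop.neuron.name] = _make_instance_set(
            pop.neuron, comps[pop.neuron.name], pop.neuron.size, seed)
    for g in model.groups:
        sets[g.instances.name] = _make_instance_set(
            g.instances, comps[g.instances.name], g.instances.size, seed)

    def port_mode(set_name, port_name):
        return comps[set_name].port(port_name).mode

    for pop in model.populations:
        src_name = pop.neuron.name
        for proj in pop.projections:
            dst_name = proj.dst_population
            n_dst = pop_sizes[dst_name]
            for k, syn in enumerate(proj.synapses):
                conn_seed = _derived_seed(seed, src_name, dst_name, k, "conn")
                c_src, c_dst, c_delay = build_connectivity(
                    syn.connectivity, pop.neuron.size, n_dst, conn_seed)
                m = c_src.size
                wu_inst = syn.weight_update.instances
                ps_inst = syn.post_synapse.instances
                if m > 0:
                    sets[wu_inst.name] = _make_instance_set(
                        wu_inst, comps[wu_inst.name], m, seed)
                else:
                    sets[wu_inst.name] = InstanceSet(
                        wu_inst.name, comps[wu_inst.name], 0, {}, {})
                sets[ps_inst.name] = _make_instance_set(
                    ps_inst, comps[ps_inst.name], n_dst, seed)
                if m > 0:
                    wu = syn.weight_update
                    ps = syn.post_synapse
                    edges.append(EdgeGroup(
                        src_name, wu.input_src_port,
                        wu_inst.name, wu.input_dst_port,
                        port_mode(src_name, wu.input_src_port),
                        c_src, np.arange(m), c_delay))
                    edges.append(EdgeGroup(
                        wu_inst.name, ps.input_src_port,
                        ps_inst.name, ps.input_dst_port,
                        port_mode(wu_inst.name, ps.input_src_port),
                        np.arange(m), c_dst, np.zeros(m)))
                    if wu.feedback_src_port is not None:
                        edges.append(EdgeGroup(
                            dst_name, wu.feedback_src_port,
                            wu_inst.name, wu.feedback_dst_port,
                            port_mode(dst_name, wu.feedback_src_port),
                            c_dst, np.arange(m), np.zeros(m)))
                ps = syn.post_synapse
                idx = np.arange(n_dst)
                edges.append(EdgeGroup(
                    ps_inst.name, ps.output_src_port,
                    dst_name, ps.output_dst_port,
                    port_mode(ps_inst.name, ps.output_src_port),
                    idx, idx.copy(), np.zeros(n_dst)))

    for i, inp in enumerate(model.inputs):
        conn_seed = _derived_seed(seed, "input", i, "conn")
        c_src, c_dst, c_delay = build_connectivity(
            inp.connectivity, sets[inp.src].size, sets[inp.dst].size, conn_seed)
        if c_src.size:
            edges.append(EdgeGroup(
                inp.src, inp.src_port, inp.dst, inp.dst_port,
                port_mode(inp.src, inp.src_port), c_src, c_dst, c_delay))

    flat = FlatModel(sets, edges)

    # every non-reduce analog receive port needs exactly one incoming edge
    diags: list[Diagnostic] = []
    for name, iset in flat.sets.items():
        for p in iset.component.ports:
            if p.mode == "analog" and p.direction == "receive" and p.reduce_op is None:
                counts = np.zeros(iset.size, dtype=np.int64)
                for e in flat.edges_into(name, p.name):
                    np.add.at(counts, e.dst_indices, 1)
                if iset.size and not np.all(counts == 1):
                    bad = int(np.flatnonzero(counts != 1)[0])
                    diags.append(Diagnostic(
                        "analog-fanin", f"{name}/{p.name}",
                        f"non-reduce analog receive port must have exactly one "
                        f"incoming edge; instance {bad} has {int(counts[bad])}"))
    if diags:
        raise ModelError("invalid elaboration", diags)
    return flat
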