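"""Shared builders: fixture components on disk and small ready-made models."""

import os

import pytest

from spineml import (ConnectivitySpec, Experiment, FixedValue, InputDriver,
                     LogRequest, NetworkModel, Population, PropertySpec,
                     ValueList, elaborate, file_loader,
                     make_exp_psc_component, make_fixed_weight_component,
                     make_gap_junction_component, make_lif_component,
                     resolve_references, write_component)
from spineml.network import ComponentInstanceSet, GenericInput, Group

LIF_PROPS = dict(v_rest=-60.0, v_thresh=-50.0, v_reset=-60.0, tau_m=20.0,
                 c_m=1.0, tau_refractory=5.0)


@pytest.fixture(scope="session")
def component_dir(tmp_path_factory):
    """Directory holding every fixture component as XML."""
    d = tmp_path_factory.mktemp("components")
    for mk in (make_lif_component, make_fixed_weight_component,
               make_exp_psc_component, make_gap_junction_component):
        comp = mk()
        write_component(comp, os.path.join(d, f"{comp.name}.xml"))
    return str(d)


def lif_population(name="N", size=1, v_init=-60.0, **overrides):
    """A population of standard LIF neurons with explicit parameters."""
    props = {**LIF_PROPS, **overrides}
    specs = [PropertySpec(k, FixedValue(v)) for k, v in props.items()]
    if isinstance(v_init, PropertySpec):
        specs.append(v_init)
    else:
        specs.append(PropertySpec("v", FixedValue(v_init)))
    return Population(neuron=ComponentInstanceSet(name, "LIF.xml", size, specs))


def single_lif_flat(component_dir, size=1, v_init=-60.0, **overrides):
    net = NetworkModel(populations=[
        lif_population(size=size, v_init=v_init, **overrides)])
    res = resolve_references(net, file_loader(component_dir))
    assert not res.diagnostics, res.diagnostics
    return elaborate(res)


def wu_psc_chain(component_dir, w=2.5, tau_syn=5.0, delay_ms=0.0):
    """One fixed-weight update feeding one exponential PSC via an impulse."""
    net = NetworkModel(
        groups=[
            Group(ComponentInstanceSet("wu", "FixedWeight.xml", 1,
                                       [PropertySpec("w", FixedValue(w))])),
            Group(ComponentInstanceSet("psc", "ExpPSC.xml", 1,
                                       [PropertySpec("tau_syn",
                                                     FixedValue(tau_syn))])),
        ],
        inputs=[GenericInput(
            "wu", "psc", "out", "impulse_in",
            ConnectivitySpec("connection_list",
                             explicit_pairs=((0, 0, delay_ms),)))],
    )
    res = resolve_references(net, file_loader(component_dir))
    assert not res.diagnostics, res.diagnostics
    return elaborate(res)


def gap_junction_network(v0=-55.0, v1=-65.0, g=0.1):
    """Two LIF neurons electrically coupled through one gap-junction instance."""
    pop = lif_population(
        size=2, v_init=PropertySpec("v", ValueList(((0, v0), (1, v1)))))
    pair = lambda s, d: ConnectivitySpec("connection_list",
                                         explicit_pairs=((s, d, 0.0),))
    return NetworkModel(
        populations=[pop],
        groups=[Group(ComponentInstanceSet(
            "gj", "GapJunction.xml", 1, [PropertySpec("g", FixedValue(g))]))],
        inputs=[
            GenericInput("N", "gj", "v", "v_pre", pair(0, 0)),
            GenericInput("N", "gj", "v", "v_post", pair(1, 0)),
            GenericInput("gj", "N", "I_pre", "I_Syn", pair(0, 0)),
            GenericInput("gj", "N", "I_post", "I_Syn", pair(0, 1)),
        ],
    )


def gap_junction_flat(component_dir, **kw):
    res = resolve_references(gap_junction_network(**kw),
                             file_loader(component_dir))
    assert not res.diagnostics, res.diagnostics
    return elaborate(res)
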