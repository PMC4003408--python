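"""Component-layer reading, validation and writing."""

import pytest

from spineml import (ComponentClass, ModelError, Parameter, Port, Regime,
                     StateVariable, make_exp_psc_component,
                     make_fixed_weight_component, make_gap_junction_component,
                     make_lif_component, read_component, validate_component,
                     write_component)
from spineml.component import Alias, OnCondition
from spineml.expr import parse_expression as pe


@pytest.fixture(params=["LIF", "FixedWeight", "ExpPSC", "GapJunction"])
def fixture_component(request):
    return {
        "LIF": make_lif_component,
        "FixedWeight": make_fixed_weight_component,
        "ExpPSC": make_exp_psc_component,
        "GapJunction": make_gap_junction_component,
    }[request.param]()


class TestReading:
    def test_lif_regimes_and_initial(self):
        comp = read_component(write_component(make_lif_component()))
        assert {r.name for r in comp.regimes} == {"integrating", "refractory"}
        assert comp.initial_regime == "integrating"
        # refractory regime holds every state variable constant
        assert comp.regime("refractory").time_derivatives == ()

    def test_psc_derivative_and_impulse_handler(self):
        comp = read_component(write_component(make_exp_psc_component()))
        (regime,) = comp.regimes
        assert regime.time_derivatives[0][0] == "I_Syn"
        (handler,) = regime.on_impulses
        # receipt of an impulse increases I_Syn by the carried value
        (var, expr) = handler.state_assignments[0]
        assert var == "I_Syn"
        assert "impulse_value" in expr.source_text

    def test_minimal_class_round_trips(self):
        comp = ComponentClass(
            name="Minimal",
            parameters=[Parameter("tau", "ms")],
            regimes=[Regime("only")],
            initial_regime="only",
        )
        again = read_component(write_component(comp))
        assert comp.structurally_equal(again)

    def test_missing_dynamics_is_schema_error(self):
        with pytest.raises(ModelError, match="Dynamics"):
            read_component('<ComponentClass name="X"/>')

    def test_unknown_element_names_path(self):
        xml = ('<ComponentClass name="X"><Bogus/>'
               '<Dynamics initial_regime="r"><Regime name="r"/></Dynamics>'
               "</ComponentClass>")
        with pytest.raises(ModelError, match="X/Bogus"):
            read_component(xml)

    def test_entity_escape_decoded(self):
        xml = write_component(make_lif_component())
        assert "&gt;" in xml  # serialized form is XML-safe
        comp = read_component(xml)
        trig = comp.regime("integrating").on_conditions[0].trigger
        assert ">" in trig.source_text and "&" not in trig.source_text


class TestValidation:
    def test_fixture_components_are_clean(self, fixture_component):
        assert validate_component(fixture_component) == []

    def test_undeclared_symbol_in_trigger(self):
        comp = make_lif_component()
        bad = comp.regimes[0].on_conditions[0]
        comp.regimes[0] = Regime(
            "integrating", comp.regimes[0].time_derivatives,
            (OnCondition(pe("foo > v_thresh"), bad.target_regime,
                         bad.state_assignments, bad.event_outputs),))
        diags = [d for d in validate_component(comp)
                 if d.rule == "unresolved-symbol"]
        assert len(diags) == 1 and "foo" in diags[0].message

    def test_unknown_initial_regime(self):
        comp = make_lif_component()
        comp.initial_regime = "nonexistent"
        assert any(d.rule == "initial-regime" for d in validate_component(comp))

    def test_duplicate_names_flagged(self):
        comp = make_lif_component()
        comp.parameters.append(Parameter("v", "mV"))  # clashes with state var
        assert any(d.rule == "duplicate-name" for d in validate_component(comp))

    def test_unknown_dimension_is_diagnostic_not_silent(self):
        comp = make_lif_component()
        comp.parameters[0] = Parameter("v_rest", "furlongs")
        assert any(d.rule == "unknown-dimension"
                   for d in validate_component(comp))

    def test_alias_cycle_detected(self):
        comp = make_lif_component()
        comp.aliases = [Alias("a", pe("b + 1")), Alias("b", pe("a * 2"))]
        assert any(d.rule == "alias-cycle" for d in validate_component(comp))

    def test_boolean_operator_rejected_in_derivative(self):
        comp = make_lif_component()
        r = comp.regimes[0]
        comp.regimes[0] = Regime(r.name, (("v", pe("v > v_thresh")),),
                                 r.on_conditions)
        assert any(d.rule == "boolean-in-arithmetic"
                   for d in validate_component(comp))

    def test_reduce_op_only_on_analog_receive(self):
        comp = make_lif_component()
        comp.ports.append(Port("bad", "send", "event", reduce_op="sum"))
        assert any(d.rule == "reduce-op-placement"
                   for d in validate_component(comp))

    def test_duplicate_derivative_in_regime(self):
        comp = make_exp_psc_component()
        r = comp.regimes[0]
        comp.regimes[0] = Regime(
            r.name, r.time_derivatives + r.time_derivatives, (), (),
            r.on_impulses)
        assert any(d.rule == "duplicate-derivative"
                   for d in validate_component(comp))


class TestWriting:
    def test_round_trip_identity(self, fixture_component):
        text = write_component(fixture_component)
        again = read_component(text)
        assert fixture_component.structurally_equal(again)
        # second pass is textually stable
        assert write_component(again) == text

    def test_refuses_invalid_component(self):
        comp = make_lif_component()
        comp.initial_regime = "bogus"
        with pytest.raises(ModelError):
            write_component(comp)

    def test_empty_alias_list_emits_no_alias_elements(self):
        comp = make_fixed_weight_component()
        assert comp.aliases == []
        assert "<Alias" not in write_component(comp)
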