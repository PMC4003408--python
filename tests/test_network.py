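"""Network layer: reading, connectivity, properties, elaboration."""

import numpy as np
import pytest

from spineml import (ConnectivitySpec, FixedValue, ModelError, NetworkModel,
                     NormalDistribution, PoissonDistribution, Population,
                     PropertySpec, UniformDistribution, ValueList,
                     build_connectivity, elaborate, file_loader,
                     instantiate_property, read_network, register_connectivity,
                     resolve_references, write_network)
from spineml.fixtures import BenchmarkSpec, make_benchmark_network
from spineml.network import (ComponentInstanceSet, _CONNECTIVITY_READERS,
                             read_connection_list_csv,
                             write_connection_list_csv)

from conftest import gap_junction_network, lif_population


class TestReadWrite:
    def test_benchmark_network_round_trip(self):
        model = make_benchmark_network(BenchmarkSpec())
        text = write_network(model)
        again = read_network(text)
        assert [p.neuron.name for p in again.populations] == \
            ["Excitatory", "Inhibitory"]
        assert again.populations[0].neuron.size == 3200
        assert write_network(again) == text

    def test_gap_junction_model_round_trip(self):
        model = gap_junction_network()
        text = write_network(model)
        again = read_network(text)
        assert write_network(again) == text
        assert len(again.inputs) == 4

    def test_unknown_connectivity_element_without_plugin(self):
        xml = """<SpineML>
          <Population>
            <Neuron name="N" url="LIF.xml" size="2"/>
            <Projection dst_population="N">
              <Synapse>
                <DistanceConnection sigma="1.0"/>
                <WeightUpdate name="w" url="FixedWeight.xml"
                  input_src_port="spike" input_dst_port="spike_in"/>
                <PostSynapse name="p" url="ExpPSC.xml"
                  input_src_port="out" input_dst_port="impulse_in"
                  output_src_port="I_Syn" output_dst_port="I_Syn"/>
              </Synapse>
            </Projection>
          </Population>
        </SpineML>"""
        with pytest.raises(ModelError) as exc:
            read_network(xml)
        assert any(d.rule == "extension-not-registered"
                   for d in exc.value.diagnostics)

    def test_registered_plugin_is_used(self):
        def read_ring(elem):
            n = int(elem.get("n"))
            pairs = tuple((i, (i + 1) % n, 0.0) for i in range(n))
            return ConnectivitySpec("connection_list", explicit_pairs=pairs)

        register_connectivity("RingConnection", read_ring)
        try:
            xml = """<SpineML>
              <Group name="g" url="ExpPSC.xml" size="3"/>
              <Group name="h" url="ExpPSC.xml" size="3"/>
              <Input src="g" dst="h" src_port="I_Syn" dst_port="impulse_in">
                <RingConnection n="3"/>
              </Input>
            </SpineML>"""
            model = read_network(xml)
            assert len(model.inputs[0].connectivity.explicit_pairs) == 3
        finally:
            del _CONNECTIVITY_READERS["RingConnection"]

    def test_connection_list_csv_round_trip(self, tmp_path):
        spec = ConnectivitySpec("connection_list",
                                explicit_pairs=((0, 1, 0.5), (2, 0, 1.0)))
        path = tmp_path / "conns.csv"
        write_connection_list_csv(spec, path)
        assert read_connection_list_csv(path) == spec


class TestResolve:
    def test_benchmark_resolves_cleanly(self, component_dir):
        model = make_benchmark_network(BenchmarkSpec())
        res = resolve_references(model, file_loader(component_dir))
        assert res.diagnostics == []
        assert res.components["Excitatory"].name == "LIF"

    def test_missing_url(self, component_dir):
        model = NetworkModel(populations=[Population(
            neuron=ComponentInstanceSet("N", "NoSuch.xml", 1))])
        res = resolve_references(model, file_loader(component_dir))
        assert any(d.rule == "missing-url" for d in res.diagnostics)

    def test_weight_update_input_to_send_port_is_direction_mismatch(
            self, component_dir):
        model = make_benchmark_network(BenchmarkSpec(n_total=10))
        wu = model.populations[0].projections[0].synapses[0].weight_update
        wu.input_dst_port = "out"  # send port on the weight update
        res = resolve_references(model, file_loader(component_dir))
        assert any(d.rule == "direction-mismatch" for d in res.diagnostics)

    def test_unknown_property_name(self, component_dir):
        model = NetworkModel(populations=[Population(
            neuron=ComponentInstanceSet(
                "N", "LIF.xml", 1,
                [PropertySpec("not_a_param", FixedValue(1.0))]))])
        res = resolve_references(model, file_loader(component_dir))
        assert any(d.rule == "unknown-property" for d in res.diagnostics)

    def test_mode_mismatch_on_generic_input(self, component_dir):
        model = gap_junction_network()
        model.inputs[0].dst_port = "v_post"
        model.inputs[0].src_port = "spike"  # event -> analog
        res = resolve_references(model, file_loader(component_dir))
        assert any(d.rule == "mode-mismatch" for d in res.diagnostics)


class TestProperties:
    def test_fixed_value_constant_vector(self):
        out = instantiate_property(PropertySpec("x", FixedValue(-60.0)), 3)
        assert list(out) == [-60.0, -60.0, -60.0]

    def test_partial_value_list_defaults_to_zero(self):
        out = instantiate_property(
            PropertySpec("x", ValueList(((2, 5.0),))), 4)
        assert list(out) == [0.0, 0.0, 5.0, 0.0]

    def test_value_list_index_out_of_range(self):
        with pytest.raises(ModelError):
            instantiate_property(PropertySpec("x", ValueList(((4, 1.0),))), 4)

    def test_normal_sample_mean_within_clt_bound(self):
        out = instantiate_property(
            PropertySpec("x", NormalDistribution(0.0, 1.0, seed=7)), 10_000)
        assert abs(out.mean()) < 4 / np.sqrt(10_000)
        assert abs(out.var() - 1.0) < 0.1

    def test_uniform_within_bounds(self):
        out = instantiate_property(
            PropertySpec("x", UniformDistribution(-60.0, -50.0, seed=3)), 1000)
        assert out.min() >= -60.0 and out.max() <= -50.0

    def test_poisson_integer_counts(self):
        out = instantiate_property(
            PropertySpec("x", PoissonDistribution(4.0, seed=5)), 1000)
        assert np.all(out == np.round(out)) and out.min() >= 0
        assert abs(out.mean() - 4.0) < 4 * np.sqrt(4.0 / 1000)

    def test_seeded_draws_are_reproducible(self):
        spec = PropertySpec("x", NormalDistribution(0.0, 2.0, seed=11))
        a = instantiate_property(spec, 100)
        b = instantiate_property(spec, 100)
        assert np.array_equal(a, b)


class TestConnectivity:
    def test_probability_zero_gives_empty(self):
        src, dst, _ = build_connectivity(
            ConnectivitySpec("fixed_probability", probability=0.0), 7, 5, 1)
        assert src.size == 0

    def test_probability_one_gives_full_cross_product(self):
        src, dst, _ = build_connectivity(
            ConnectivitySpec("fixed_probability", probability=1.0), 3, 4, 1)
        assert src.size == 12
        assert set(zip(src, dst)) == {(i, j) for i in range(3)
                                      for j in range(4)}

    def test_one_to_one_requires_equal_sizes(self):
        with pytest.raises(ModelError):
            build_connectivity(ConnectivitySpec("one_to_one"), 3, 4, 1)

    def test_one_to_one_diagonal(self):
        src, dst, delay = build_connectivity(
            ConnectivitySpec("one_to_one", delay_ms=1.5), 4, 4, 1)
        assert np.array_equal(src, dst) and np.all(delay == 1.5)

    def test_fixed_probability_count_within_binomial_bound(self):
        n, p = 800, 0.02
        N = n * n
        sigma = np.sqrt(N * p * (1 - p))
        for seed in range(5):
            src, _, _ = build_connectivity(
                ConnectivitySpec("fixed_probability", probability=p),
                n, n, seed)
            assert abs(src.size - N * p) < 4 * sigma

    def test_deterministic_for_fixed_seed(self):
        spec = ConnectivitySpec("fixed_probability", probability=0.1, seed=42)
        a = build_connectivity(spec, 50, 50, 99)
        b = build_connectivity(spec, 50, 50, 7)  # embedded seed wins
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestElaboration:
    def _two_neuron_model(self, kind="one_to_one"):
        spec = BenchmarkSpec(n_total=10)
        model = make_benchmark_network(spec)
        model.populations = model.populations[:1]
        pop = model.populations[0]
        pop.neuron.size = 2
        pop.projections = [p for p in pop.projections
                           if p.dst_population == "Excitatory"]
        syn = pop.projections[0].synapses[0]
        syn.connectivity = ConnectivitySpec(kind)
        return model

    def test_one_to_one_counts_match_hand_enumeration(self, component_dir):
        # 2 pre, 2 post, one_to_one: hand enumeration gives 2 weight-update
        # instances, 2 post-synapse instances and 2 bindings per chain stage
        model = self._two_neuron_model()
        res = resolve_references(model, file_loader(component_dir))
        assert not res.diagnostics, res.diagnostics
        flat = elaborate(res)
        assert flat.sets["Excitatory_Excitatory_wu"].size == 2
        assert flat.sets["Excitatory_Excitatory_psc"].size == 2
        assert flat.n_edges == 6

    def test_instance_count_law(self, component_dir):
        model = make_benchmark_network(BenchmarkSpec(n_total=200, seed=5))
        res = resolve_references(model, file_loader(component_dir))
        flat = elaborate(res, seed=5)
        for pop in model.populations:
            for proj in pop.projections:
                for syn in proj.synapses:
                    wu = flat.sets[syn.weight_update.instances.name]
                    ps = flat.sets[syn.post_synapse.instances.name]
                    pre_wu = flat.edges_into(wu.name,
                                             syn.weight_update.input_dst_port)
                    assert sum(len(e) for e in pre_wu) == wu.size
                    assert ps.size == flat.sets[proj.dst_population].size

    def test_gap_junction_fixture_has_four_analog_edges(self, component_dir):
        from conftest import gap_junction_flat

        flat = gap_junction_flat(component_dir)
        assert flat.n_edges == 4
        assert all(e.mode == "analog" for e in flat.edges)

    def test_empty_projection_list(self, component_dir):
        model = NetworkModel(populations=[lif_population(size=3)])
        res = resolve_references(model, file_loader(component_dir))
        flat = elaborate(res)
        assert flat.sets["N"].size == 3 and flat.n_edges == 0

    def test_probability_zero_elaborates_with_no_synaptic_edges(
            self, component_dir):
        model = self._two_neuron_model()
        syn = model.populations[0].projections[0].synapses[0]
        syn.connectivity = ConnectivitySpec("fixed_probability",
                                            probability=0.0)
        res = resolve_references(model, file_loader(component_dir))
        flat = elaborate(res)
        assert flat.sets["Excitatory_Excitatory_wu"].size == 0
        # only the post-synapse -> neuron analogue stage remains
        assert all(e.mode == "analog" for e in flat.edges)

    def test_same_seed_bitwise_identical(self, component_dir):
        model = make_benchmark_network(BenchmarkSpec(n_total=100))
        res = resolve_references(model, file_loader(component_dir))
        a = elaborate(res, seed=3)
        b = elaborate(res, seed=3)
        for name in a.sets:
            for k in a.sets[name].parameters:
                assert np.array_equal(a.sets[name].parameters[k],
                                      b.sets[name].parameters[k])
            for k in a.sets[name].initial_state:
                assert np.array_equal(a.sets[name].initial_state[k],
                                      b.sets[name].initial_state[k])
        assert len(a.edges) == len(b.edges)
        for ea, eb in zip(a.edges, b.edges):
            assert np.array_equal(ea.src_indices, eb.src_indices)
            assert np.array_equal(ea.dst_indices, eb.dst_indices)
            assert np.array_equal(ea.delays_ms, eb.delays_ms)

    def test_fan_in_violation_on_plain_analog_port(self, component_dir):
        # a gap junction with only one of its two voltage inputs wired
        model = gap_junction_network()
        model.inputs = model.inputs[1:]
        res = resolve_references(model, file_loader(component_dir))
        with pytest.raises(ModelError) as exc:
            elaborate(res)
        assert any(d.rule == "analog-fanin" for d in exc.value.diagnostics)
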