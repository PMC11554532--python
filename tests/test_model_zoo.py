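"""Structure, shape inference and serialization of the two architectures."""

import json

import numpy as np
import pytest

from planefusion.model_zoo import (
    ConfigurationError,
    GraphError,
    LayerSpec,
    ModelGraph,
    build_four_residual_model,
    build_three_residual_model,
    deserialize_graph,
    infer_shapes,
    serialize_graph,
)


def n_of_kind(graph, kind):
    return sum(1 for spec in graph.layers if spec.kind == kind)


class TestBuilders:
    @pytest.mark.parametrize(
        "builder,n_add,n_bn",
        [(build_three_residual_model, 3, 0), (build_four_residual_model, 4, 4)],
    )
    def test_block_structure_and_gap_width(self, builder, n_add, n_bn):
        graph = builder(4, (224, 224, 3))
        assert n_of_kind(graph, "add") == n_add
        assert n_of_kind(graph, "batchnorm") == n_bn
        report = infer_shapes(graph)
        assert report.gap_width == 2048

    def test_head_depends_only_on_num_classes(self):
        g2 = build_three_residual_model(2)
        g4 = build_three_residual_model(4)
        body2 = [(s.name, s.kind, s.depth) for s in g2.layers if s.kind != "fc"]
        body4 = [(s.name, s.kind, s.depth) for s in g4.layers if s.kind != "fc"]
        assert body2 == body4
        assert g2.layer("fc").depth == 2
        assert g4.layer("fc").depth == 4

    def test_width_scale_shrinks_gap(self):
        graph = build_three_residual_model(4, (64, 64, 3), width_scale=1 / 16)
        assert infer_shapes(graph).gap_width == 128

    @pytest.mark.parametrize("shape", [(16, 16, 3), (31, 224, 3)])
    def test_small_input_rejected_naming_dimension(self, shape):
        with pytest.raises(ConfigurationError, match="32"):
            build_three_residual_model(4, shape)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            build_four_residual_model(1)

    @pytest.mark.parametrize(
        "builder", [build_three_residual_model, build_four_residual_model]
    )
    def test_graphs_are_valid_dags(self, builder):
        graph = builder(6)
        graph.validate()
        order = graph.topological_order()
        assert order[0] == "input" and graph.layer(order[-1]).kind == "softmax"


class TestInferShapes:
    def _wrap(self, layers, edges, input_shape=(224, 224, 3), k=4):
        return ModelGraph(layers=layers, edges=edges, num_classes=k, input_shape=input_shape)

    def test_single_conv_shape_and_params(self):
        graph = self._wrap(
            [
                LayerSpec("input", "input"),
                LayerSpec("c", "conv", depth=32, kernel=3, stride=2, padding_mode="same"),
                LayerSpec("g", "gap"),
                LayerSpec("f", "fc", depth=4),
                LayerSpec("s", "softmax"),
            ],
            [("input", "c"), ("c", "g"), ("g", "f"), ("f", "s")],
        )
        report = infer_shapes(graph)
        assert report.shapes["c"] == (112, 112, 32)
        assert report.param_counts["c"] == 3 * 3 * 3 * 32 + 32 == 896
        assert report.param_counts["f"] == 32 * 4 + 4

    def test_fc_param_count(self):
        graph = self._wrap(
            [
                LayerSpec("input", "input"),
                LayerSpec("g", "gap"),
                LayerSpec("f", "fc", depth=4),
                LayerSpec("s", "softmax"),
            ],
            [("input", "g"), ("g", "f"), ("f", "s")],
            input_shape=(1, 1, 2048),
        )
        assert infer_shapes(graph).param_counts["f"] == 2048 * 4 + 4 == 8196

    def test_add_shape_mismatch_names_layer(self):
        layers = [
            LayerSpec("input", "input"),
            LayerSpec("c1", "conv", depth=8, kernel=3, stride=2, padding_mode="same"),
            LayerSpec("c2", "conv", depth=4, kernel=3, stride=1, padding_mode="same"),
            LayerSpec("bad_add", "add"),
            LayerSpec("g", "gap"),
            LayerSpec("f", "fc", depth=4),
            LayerSpec("s", "softmax"),
        ]
        edges = [
            ("input", "c1"),
            ("c1", "c2"),
            ("c2", "bad_add"),
            ("input", "bad_add"),
            ("bad_add", "g"),
            ("g", "f"),
            ("f", "s"),
        ]
        with pytest.raises(GraphError, match="bad_add"):
            infer_shapes(ModelGraph(layers, edges, 4, (64, 64, 3)))

    def test_parameter_accounting_matches_brute_force(self):
        graph = build_four_residual_model(4, (224, 224, 3))
        report = infer_shapes(graph)
        total = 0
        for spec in graph.layers:
            pred = graph.predecessors(spec.name)
            cin = report.shapes[pred[0]][2] if pred else None
            if spec.kind == "conv":
                total += spec.kernel**2 * cin * spec.depth + spec.depth
            elif spec.kind == "fc":
                total += cin * spec.depth + spec.depth
            elif spec.kind == "batchnorm":
                total += 2 * cin
        assert report.total_params == total


class TestSerialization:
    def test_round_trip_identity(self):
        graph = build_three_residual_model(4)
        back = deserialize_graph(serialize_graph(graph))
        assert back.layers == graph.layers
        assert back.edges == graph.edges
        assert back.num_classes == graph.num_classes
        assert back.input_shape == graph.input_shape

    def test_missing_edges_field_is_parse_error(self):
        doc = json.loads(serialize_graph(build_three_residual_model(4)))
        del doc["edges"]
        with pytest.raises(GraphError, match="edges"):
            deserialize_graph(doc)

    def test_hand_written_two_layer_document(self):
        doc = {
            "input_shape": [32, 32, 1],
            "num_classes": 2,
            "layers": [
                {"name": "input", "kind": "input"},
                {"name": "s", "kind": "softmax"},
            ],
            "edges": [["input", "s"]],
        }
        graph = deserialize_graph(json.dumps(doc))
        assert len(graph.layers) == 2

    def test_malformed_layer_reports_path(self):
        doc = {
            "input_shape": [32, 32, 1],
            "num_classes": 2,
            "layers": [{"name": "input", "kind": "input"}, {"kind": "softmax"}],
            "edges": [],
        }
        with pytest.raises(GraphError, match=r"layers\[1\]"):
            deserialize_graph(doc)
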