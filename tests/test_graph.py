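"""Symbolic graph: shape propagation, parameter accounting, reference audit."""

import numpy as np
import pytest

from davsnet.graph import (
    GraphError,
    LayerSpec,
    NetworkGraph,
    ParamAudit,
    TensorShape,
    audit_against_reference,
    build_davsnet_graph,
    count_parameters,
    format_audit,
    format_audit_report,
    graph_from_json,
    graph_to_json,
    propagate_shapes,
    validate_structure,
)


class TestShapePropagation:
    @pytest.mark.parametrize(
        "layer, expected",
        [
            ("EDB1-Cat", (640, 640, 128)),  # concat of two 64-channel maps
            ("Pool-3", (80, 80, 256)),  # feature map before upsampling
            ("Unpool-3", (160, 160, 256)),  # unpool restores partner pool input size
            ("DDB3-Cat", (160, 160, 640)),  # 256 + 128 + 256-channel skip
            ("DDB2-Cat", (320, 320, 320)),
            ("DDB1-Cat", (640, 640, 130)),
            ("softmax", (640, 640, 2)),
        ],
    )
    def test_canonical_shapes(self, canonical_shapes, layer, expected):
        s = canonical_shapes[layer]
        assert (s.height, s.width, s.channels) == expected

    def test_smallest_valid_input(self):
        g = build_davsnet_graph(TensorShape(8, 8, 3))
        shapes = propagate_shapes(g)
        s = shapes["pixel_classification"]
        assert (s.height, s.width, s.channels) == (8, 8, 2)
        assert (shapes["Pool-3"].height, shapes["Pool-3"].width) == (1, 1)

    def test_non_divisible_input_rejected(self):
        with pytest.raises(GraphError, match="divisible by 8"):
            build_davsnet_graph(TensorShape(100, 640, 3))

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(GraphError, match="3 channels"):
            build_davsnet_graph(TensorShape(640, 640, 4))

    def test_concat_spatial_mismatch_names_offenders(self):
        layers = [
            LayerSpec("a", "convolution", ("input",), kernel=(3, 3), filters=4),
            LayerSpec("p", "max_pool", ("a",), kernel=(2, 2), stride=(2, 2)),
            LayerSpec("bad", "depth_concat", ("a", "p")),
        ]
        g = NetworkGraph(layers=layers, input_shape=TensorShape(8, 8, 3))
        with pytest.raises(GraphError) as err:
            propagate_shapes(g)
        assert "a" in str(err.value) and "p" in str(err.value)

    def test_concat_channel_sum_property(self, canonical_graph, canonical_shapes):
        """Depth concatenation output channels are the sum of input channels
        and the spatial extent is unchanged."""
        for spec in canonical_graph:
            if spec.kind != "depth_concat":
                continue
            out = canonical_shapes[spec.name]
            ins = [canonical_shapes[i] for i in spec.inputs]
            assert out.channels == sum(i.channels for i in ins)
            assert all((i.height, i.width) == (out.height, out.width) for i in ins)

    @pytest.mark.parametrize("side", [8, 16, 64, 640])
    def test_pool_unpool_duality(self, side):
        """Each unpool output recovers its partner pool's input spatial size."""
        g = build_davsnet_graph(TensorShape(side, side, 3))
        shapes = propagate_shapes(g)
        for k in (1, 2, 3):
            pool_in = shapes[g.layer(f"Pool-{k}").inputs[0]]
            unpool_out = shapes[f"Unpool-{k}"]
            assert (unpool_out.height, unpool_out.width) == (pool_in.height, pool_in.width)
            assert (shapes[f"Pool-{k}"].height * 2) == pool_in.height


class TestStructure:
    def test_canonical_constraints(self, canonical_graph):
        counts = validate_structure(canonical_graph)
        assert counts["conv3x3"] == 12
        assert counts["bottleneck1x1"] == 6
        assert counts["max_pool"] == counts["max_unpool"] == 3
        assert counts["depth_concat"] == 6

    def test_unknown_input_rejected(self):
        with pytest.raises(GraphError, match="earlier layer"):
            NetworkGraph(
                layers=[LayerSpec("a", "relu", ("ghost",))],
                input_shape=TensorShape(8, 8, 3),
            )

    def test_duplicate_names_rejected(self):
        layers = [
            LayerSpec("a", "relu", ("input",)),
            LayerSpec("a", "relu", ("input",)),
        ]
        with pytest.raises(GraphError, match="duplicate"):
            NetworkGraph(layers=layers, input_shape=TensorShape(8, 8, 3))

    def test_layer_spec_validation(self):
        with pytest.raises(GraphError, match="kernel and filters"):
            LayerSpec("c", "convolution", ("input",))
        with pytest.raises(GraphError, match="at least 2"):
            LayerSpec("cat", "depth_concat", ("input",))
        with pytest.raises(GraphError, match="partner"):
            LayerSpec("u", "max_unpool", ("input",))

    def test_json_round_trip(self, canonical_graph, canonical_shapes):
        g2 = graph_from_json(graph_to_json(canonical_graph))
        assert [s.name for s in g2] == [s.name for s in canonical_graph]
        assert propagate_shapes(g2) == canonical_shapes


def _brute_force_count(kernel, cin, cout):
    """One scalar per weight/bias slot, enumerated explicitly."""
    kh, kw = kernel
    slots = 0
    for _ in range(kh):
        for _ in range(kw):
            slots += cin * cout
    return slots + cout  # one bias per filter


class TestParameterCounts:
    @pytest.mark.parametrize(
        "layer, expected",
        [
            ("EDB1-C1", 1792),  # 3x3x3 -> 64
            ("EDB1-C2", 36928),
            ("E-Bneck-1", 8256),
            ("EDB2-C1", 73856),
            ("EDB2-C2", 147584),
            ("E-Bneck-2", 32896),  # reconciled 256 -> 128
            ("EDB3-C1", 295168),
            ("EDB3-C2", 590080),
            ("E-Bneck-3", 131328),
            ("DDB3-C1", 590080),
            ("DDB3-C2", 295040),  # 128 filters so the concat depth is 640
            ("D-Bneck-1", 82048),
            ("DDB2-C1", 147584),
            ("DDB2-C2", 73792),
            ("D-Bneck-2", 20544),
            ("DDB1-C1", 36928),
            ("DDB1-C2", 1154),
            ("D-Bneck-3", 262),  # 1x1, 130 -> 2 classes
        ],
    )
    def test_canonical_layer_counts(self, canonical_audit, layer, expected):
        assert canonical_audit.record(layer).conv_params == expected

    def test_bn_counts_scale_and_shift_only(self, canonical_audit):
        assert canonical_audit.record("EDB1-C1-bn").bn_params == 128
        assert canonical_audit.record("D-Bneck-3-bn").bn_params == 4

    def test_identity_one_channel_bottleneck(self):
        """1x1 convolution with one input and one output channel: 2 params."""
        layers = [LayerSpec("b", "convolution", ("input",), kernel=(1, 1), filters=1)]
        g = NetworkGraph(layers=layers, input_shape=TensorShape(8, 8, 1))
        audit = count_parameters(g)
        assert audit.record("b").total == 2

    def test_count_matches_brute_force_enumeration(self, rng):
        """Random small conv specs against one-scalar-per-slot enumeration."""
        for _ in range(25):
            kh, kw = rng.choice([1, 3]), rng.choice([1, 3])
            cin = int(rng.integers(1, 9))
            cout = int(rng.integers(1, 9))
            layers = [
                LayerSpec("c", "convolution", ("input",), kernel=(int(kh), int(kw)), filters=cout)
            ]
            g = NetworkGraph(layers=layers, input_shape=TensorShape(8, 8, cin))
            assert count_parameters(g).record("c").conv_params == _brute_force_count(
                (kh, kw), cin, cout
            )

    def test_total_is_sum_of_records(self, canonical_audit):
        assert canonical_audit.total == sum(r.total for r in canonical_audit.records)


class TestReferenceAudit:
    def test_all_consistent_rows_match(self, canonical_audit):
        entries = audit_against_reference(canonical_audit)
        assert len(entries) == 18
        assert not any(e.status == "MISMATCH" for e in entries)
        by_layer = {e.layer: e for e in entries}
        assert by_layer["EDB2-C2"].status == "MATCH"
        assert by_layer["EDB2-C2"].computed_conv == 147584

    def test_typographical_rows_reconciled_not_altered(self, canonical_audit):
        by_layer = {e.layer: e for e in audit_against_reference(canonical_audit)}
        eb2 = by_layer["E-Bneck-2"]
        assert eb2.status == "RECONCILED"
        assert eb2.computed_conv == 32896
        assert eb2.printed_conv == 8256  # printed text preserved alongside
        ddb3c2 = by_layer["DDB3-C2"]
        assert ddb3c2.status == "RECONCILED"
        assert ddb3c2.computed_conv == ddb3c2.printed_conv == 295040
        assert "128" in ddb3c2.note

    def test_decoder_label_typos_noted(self, canonical_audit):
        by_layer = {e.layer: e for e in audit_against_reference(canonical_audit)}
        assert "EDB2-C1" in by_layer["DDB2-C1"].note
        assert by_layer["DDB2-C1"].status == "MATCH"

    def test_empty_audit_empty_report(self):
        empty = ParamAudit(records=[], total=0)
        assert audit_against_reference(empty) == []

    def test_text_exports_render(self, canonical_graph, canonical_audit):
        table = format_audit(canonical_audit, canonical_graph)
        report = format_audit_report(audit_against_reference(canonical_audit))
        assert "EDB1-C1" in table and "total" in table
        assert "RECONCILED" in report and "0 MISMATCH" in report
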