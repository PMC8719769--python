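"""Declarative architecture graph for the densely aggregating vessel
segmentation network (DAVS-Net).

The network is described symbolically as an ordered, acyclic list of
:class:`LayerSpec` records.  From that description alone the module can
propagate activation shapes, count trainable parameters layer by layer,
and compare the result against the published per-layer reference table —
no deep-learning runtime is involved.  The executable model
(:mod:`davsnet.model`) consumes the same graph, so the audit and the
runtime can never drift apart.

Architecture summary
--------------------
Encoder: three dense blocks.  Block *i* applies Conv-A (3x3) -> BN ->
ReLU, Conv-B (3x3), concatenates both convolution outputs depth-wise,
applies BN -> ReLU, reduces channels with a 1x1 bottleneck (BN -> ReLU),
and halves the spatial size with a 2x2/2 max-pool whose argmax indices
are retained.  Channel plan: 64/64 -> cat 128 -> bneck 64;
128/128 -> cat 256 -> bneck 128; 256/256 -> cat 512 -> bneck 256.

Decoder: mirror image.  Block *k* starts with a max-unpool driven by the
indices of the mirrored encoder pool, applies Conv-A/Conv-B, and
concatenates Conv-A out, Conv-B out and the mirrored encoder block's
Conv-A activation (the "outer dense path" carrying edge information),
followed by BN -> ReLU and a 1x1 bottleneck.  Channel plan:
256/128 -> cat 640 -> bneck 128; 128/64 -> cat 320 -> bneck 64;
64/2 -> cat 130 -> bneck 2 -> softmax -> per-pixel classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "TensorShape",
    "LayerSpec",
    "NetworkGraph",
    "ParamRecord",
    "ParamAudit",
    "AuditEntry",
    "GraphError",
    "LAYER_KINDS",
    "INPUT_NAME",
    "build_davsnet_graph",
    "propagate_shapes",
    "count_parameters",
    "audit_against_reference",
    "validate_structure",
    "format_audit",
    "format_audit_report",
    "graph_to_json",
    "graph_from_json",
]

LAYER_KINDS = frozenset(
    {
        "convolution",
        "batch_norm",
        "relu",
        "depth_concat",
        "max_pool",
        "max_unpool",
        "softmax",
        "pixel_classification",
    }
)

#: Reserved pseudo-layer name referring to the network input.
INPUT_NAME = "input"


class GraphError(ValueError):
    """Raised when a graph violates its structural invariants."""


@dataclass(frozen=True)
class TensorShape:
    """Spatial extent and channel depth of an activation volume."""

    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        for name in ("height", "width", "channels"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise GraphError(f"TensorShape.{name} must be a positive integer, got {v!r}")

    def __str__(self) -> str:
        return f"{self.height}x{self.width}x{self.channels}"


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network graph.

    ``partner`` is only meaningful for ``max_unpool`` layers and names the
    ``max_pool`` layer whose argmax indices drive the unpooling.
    """

    name: str
    kind: str
    inputs: tuple[str, ...]
    kernel: Optional[tuple[int, int]] = None
    stride: Optional[tuple[int, int]] = None
    filters: Optional[int] = None
    partner: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise GraphError(f"unknown layer kind {self.kind!r} for layer {self.name!r}")
        if not self.inputs:
            raise GraphError(f"layer {self.name!r} has no inputs")
        if self.kind == "convolution" and (self.kernel is None or self.filters is None):
            raise GraphError(f"convolution {self.name!r} requires kernel and filters")
        if self.kind == "depth_concat" and len(self.inputs) < 2:
            raise GraphError(f"depth_concat {self.name!r} needs at least 2 inputs")
        if self.kind == "max_unpool" and self.partner is None:
            raise GraphError(f"max_unpool {self.name!r} must name its max_pool partner")


@dataclass
class NetworkGraph:
    """Ordered, acyclic layer graph with a fixed input shape.

    Layers may reference :data:`INPUT_NAME` or any *earlier* layer by
    name; the ordering requirement is what guarantees acyclicity.
    """

    layers: list[LayerSpec]
    input_shape: TensorShape
    class_count: int = 2

    def __post_init__(self) -> None:
        self._by_name = {}
        seen = {INPUT_NAME}
        for spec in self.layers:
            if spec.name in self._by_name or spec.name == INPUT_NAME:
                raise GraphError(f"duplicate layer name {spec.name!r}")
            for inp in spec.inputs:
                if inp not in seen:
                    raise GraphError(
                        f"layer {spec.name!r} references {inp!r} which is not an "
                        "earlier layer (graph must be ordered and acyclic)"
                    )
            if spec.kind == "max_unpool":
                pool = self._by_name.get(spec.partner)
                if pool is None or pool.kind != "max_pool":
                    raise GraphError(
                        f"max_unpool {spec.name!r} partner {spec.partner!r} "
                        "is not an earlier max_pool layer"
                    )
            self._by_name[spec.name] = spec
            seen.add(spec.name)

    def layer(self, name: str) -> LayerSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.layers)


def _enc_block(layers: list[LayerSpec], idx: int, in_name: str, width: int) -> str:
    """Append encoder dense block ``idx`` and return the pool layer name."""
    c1, c2 = f"EDB{idx}-C1", f"EDB{idx}-C2"
    layers += [
        LayerSpec(c1, "convolution", (in_name,), kernel=(3, 3), stride=(1, 1), filters=width),
        LayerSpec(f"{c1}-bn", "batch_norm", (c1,)),
        LayerSpec(f"{c1}-relu", "relu", (f"{c1}-bn",)),
        LayerSpec(c2, "convolution", (f"{c1}-relu",), kernel=(3, 3), stride=(1, 1), filters=width),
        LayerSpec(f"EDB{idx}-Cat", "depth_concat", (f"{c1}-relu", c2)),
        LayerSpec(f"EDB{idx}-Cat-bn", "batch_norm", (f"EDB{idx}-Cat",)),
        LayerSpec(f"EDB{idx}-Cat-relu", "relu", (f"EDB{idx}-Cat-bn",)),
        LayerSpec(f"E-Bneck-{idx}", "convolution", (f"EDB{idx}-Cat-relu",), kernel=(1, 1), stride=(1, 1), filters=width),
        LayerSpec(f"E-Bneck-{idx}-bn", "batch_norm", (f"E-Bneck-{idx}",)),
        LayerSpec(f"E-Bneck-{idx}-relu", "relu", (f"E-Bneck-{idx}-bn",)),
        LayerSpec(f"Pool-{idx}", "max_pool", (f"E-Bneck-{idx}-relu",), kernel=(2, 2), stride=(2, 2)),
    ]
    return f"Pool-{idx}"


def _dec_block(
    layers: list[LayerSpec],
    block: int,
    bneck: int,
    in_name: str,
    width_a: int,
    width_b: int,
    bneck_width: int,
) -> str:
    """Append decoder dense block ``DDB{block}`` and return its bottleneck ReLU."""
    c1, c2 = f"DDB{block}-C1", f"DDB{block}-C2"
    bn_name = f"D-Bneck-{bneck}"
    layers += [
        LayerSpec(f"Unpool-{block}", "max_unpool", (in_name,), kernel=(2, 2), stride=(2, 2), partner=f"Pool-{block}"),
        LayerSpec(c1, "convolution", (f"Unpool-{block}",), kernel=(3, 3), stride=(1, 1), filters=width_a),
        LayerSpec(f"{c1}-bn", "batch_norm", (c1,)),
        LayerSpec(f"{c1}-relu", "relu", (f"{c1}-bn",)),
        LayerSpec(c2, "convolution", (f"{c1}-relu",), kernel=(3, 3), stride=(1, 1), filters=width_b),
        # outer dense path: the mirrored encoder block's Conv-A activation
        LayerSpec(f"DDB{block}-Cat", "depth_concat", (f"{c1}-relu", c2, f"EDB{block}-C1-relu")),
        LayerSpec(f"DDB{block}-Cat-bn", "batch_norm", (f"DDB{block}-Cat",)),
        LayerSpec(f"DDB{block}-Cat-relu", "relu", (f"DDB{block}-Cat-bn",)),
        LayerSpec(bn_name, "convolution", (f"DDB{block}-Cat-relu",), kernel=(1, 1), stride=(1, 1), filters=bneck_width),
        LayerSpec(f"{bn_name}-bn", "batch_norm", (bn_name,)),
        LayerSpec(f"{bn_name}-relu", "relu", (f"{bn_name}-bn",)),
    ]
    return f"{bn_name}-relu"


def build_davsnet_graph(input_shape: TensorShape) -> NetworkGraph:
    """Construct the canonical network graph for a given input shape.

    The input must have 3 channels and spatial dimensions divisible by 8
    (three 2x halvings).
    """
    if input_shape.channels != 3:
        raise GraphError(f"input must have 3 channels, got {input_shape.channels}")
    if input_shape.height % 8 or input_shape.width % 8:
        raise GraphError(
            f"input spatial size {input_shape.height}x{input_shape.width} must be "
            "divisible by 8: the encoder halves the resolution three times"
        )

    layers: list[LayerSpec] = []
    prev = INPUT_NAME
    for idx, width in ((1, 64), (2, 128), (3, 256)):
        prev = _enc_block(layers, idx, prev, width)
    # decoder blocks run deepest-first; bottlenecks are numbered in
    # execution order (D-Bneck-1 follows DDB3, D-Bneck-3 follows DDB1)
    prev = _dec_block(layers, 3, 1, prev, 256, 128, 128)
    prev = _dec_block(layers, 2, 2, prev, 128, 64, 64)
    prev = _dec_block(layers, 1, 3, prev, 64, 2, 2)
    layers += [
        LayerSpec("softmax", "softmax", (prev,)),
        LayerSpec("pixel_classification", "pixel_classification", ("softmax",)),
    ]
    return NetworkGraph(layers=layers, input_shape=input_shape, class_count=2)


def propagate_shapes(graph: NetworkGraph) -> dict[str, TensorShape]:
    """Assign an output shape to every layer.

    3x3 convolutions are same-padded and stride 1, hence spatial-size
    preserving; pooling halves height and width; unpooling restores the
    partner pool's input size; depth concatenation sums channel counts
    and requires identical spatial extents.
    """
    shapes: dict[str, TensorShape] = {INPUT_NAME: graph.input_shape}
    for spec in graph:
        ins = [shapes[i] for i in spec.inputs]
        if spec.kind == "convolution":
            s = ins[0]
            out = TensorShape(s.height, s.width, spec.filters)
        elif spec.kind == "depth_concat":
            hw = {(s.height, s.width) for s in ins}
            if len(hw) > 1:
                offenders = ", ".join(f"{n}={shapes[n]}" for n in spec.inputs)
                raise GraphError(
                    f"depth_concat {spec.name!r} has mismatched spatial sizes: {offenders}"
                )
            s = ins[0]
            out = TensorShape(s.height, s.width, sum(i.channels for i in ins))
        elif spec.kind == "max_pool":
            s = ins[0]
            if s.height % 2 or s.width % 2:
                raise GraphError(f"max_pool {spec.name!r} input {s} not divisible by 2")
            out = TensorShape(s.height // 2, s.width // 2, s.channels)
        elif spec.kind == "max_unpool":
            pool_in = shapes[graph.layer(spec.partner).inputs[0]]
            s = ins[0]
            if s.channels != pool_in.channels:
                raise GraphError(
                    f"max_unpool {spec.name!r} channel depth {s.channels} does not "
                    f"match partner pool input depth {pool_in.channels}"
                )
            out = TensorShape(pool_in.height, pool_in.width, s.channels)
        else:  # batch_norm, relu, softmax, pixel_classification: shape-preserving
            out = ins[0]
        shapes[spec.name] = out
    return shapes


@dataclass(frozen=True)
class ParamRecord:
    """Trainable-parameter tally for one layer."""

    name: str
    kind: str
    weight_params: int
    bias_params: int
    bn_params: int
    output_shape: TensorShape

    @property
    def conv_params(self) -> int:
        """Weights + biases, the convention of the reference table's main cell."""
        return self.weight_params + self.bias_params

    @property
    def total(self) -> int:
        return self.weight_params + self.bias_params + self.bn_params


@dataclass
class ParamAudit:
    """Per-layer parameter accounting for a graph."""

    records: list[ParamRecord]
    total: int

    def __post_init__(self) -> None:
        assert self.total == sum(r.total for r in self.records)

    def record(self, name: str) -> ParamRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.records)


def count_parameters(graph: NetworkGraph, shapes: Optional[Mapping[str, TensorShape]] = None) -> ParamAudit:
    """Count trainable parameters of every layer.

    Conventions: a convolution holds ``kh*kw*Cin*Cout`` weights plus
    ``Cout`` biases; batch normalisation holds the learnable scale and
    shift (``2*C``; running statistics are not trainable and not
    counted); every other kind is parameter-free.
    """
    if shapes is None:
        shapes = propagate_shapes(graph)
    records = []
    for spec in graph:
        w = b = bn = 0
        out = shapes[spec.name]
        if spec.kind == "convolution":
            cin = shapes[spec.inputs[0]].channels
            kh, kw = spec.kernel
            w = kh * kw * cin * spec.filters
            b = spec.filters
        elif spec.kind == "batch_norm":
            bn = 2 * out.channels
        records.append(ParamRecord(spec.name, spec.kind, w, b, bn, out))
    return ParamAudit(records=records, total=sum(r.total for r in records))


def validate_structure(graph: NetworkGraph) -> dict[str, int]:
    """Check the canonical structural constraints and return the tallies.

    The architecture uses exactly 12 3x3 convolutions (two per dense
    block, six blocks), 6 1x1 bottleneck convolutions, 3 pool / 3 unpool
    pairs and 6 depth concatenations.
    """
    counts = {
        "conv3x3": sum(1 for s in graph if s.kind == "convolution" and s.kernel == (3, 3)),
        "bottleneck1x1": sum(1 for s in graph if s.kind == "convolution" and s.kernel == (1, 1)),
        "max_pool": sum(1 for s in graph if s.kind == "max_pool"),
        "max_unpool": sum(1 for s in graph if s.kind == "max_unpool"),
        "depth_concat": sum(1 for s in graph if s.kind == "depth_concat"),
        "dense_blocks": sum(1 for s in graph if s.kind == "depth_concat"),
    }
    expected = {
        "conv3x3": 12,
        "bottleneck1x1": 6,
        "max_pool": 3,
        "max_unpool": 3,
        "depth_concat": 6,
        "dense_blocks": 6,
    }
    bad = {k: (counts[k], expected[k]) for k in expected if counts[k] != expected[k]}
    if bad:
        raise GraphError(f"structural constraint violations (got, expected): {bad}")
    return counts


# ---------------------------------------------------------------------------
# Reference audit: the published per-layer table, transcribed verbatim.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PrintedRow:
    """One parameter-bearing row of the published layer table, as printed.

    ``printed_conv`` is the weights+biases cell, ``printed_bn`` the "+2C"
    batch-norm term (None when the row carries no BN marker),
    ``printed_output``/``printed_filters`` the shape and filter cells.
    ``printed_label`` records the label as it appears when it differs
    from the layer it evidently describes. ``typo`` marks rows whose
    parameter or filter cells are arithmetically inconsistent with the
    rest of the table and are reconciled rather than matched.
    """

    layer: str
    printed_conv: int
    printed_bn: Optional[int]
    printed_filters: Optional[int]
    printed_output: tuple[int, int, int]
    printed_label: Optional[str] = None
    typo: Optional[str] = None


# Transcribed reference rows (canonical 640x640x3 input). Known
# inconsistencies, reconciled by cross-checking neighbouring cells:
#  * E-Bneck-2 is printed as a copy of the E-Bneck-1 row ("8256 + 128",
#    output 640x640x64) although Pool-2's printed 160x160x128 output and
#    the next block's printed 295,168 parameters both force a 256->128
#    channel bottleneck (32,896 + 256).
#  * DDB3-C2's filters cell prints 64 although its parameter cell
#    (295,040) and the concat depth 640 = 256+128+256 force 128 filters.
#  * The two convolution rows of decoder block 2 are printed with
#    encoder labels (EDB2-C1/EDB2-C2).
#  * Several output cells disagree with their own row's filter count
#    (noted per row); parameters there are self-consistent.
_TABLE_REFERENCE: tuple[_PrintedRow, ...] = (
    _PrintedRow("EDB1-C1", 1792, 128, 64, (640, 640, 64)),
    _PrintedRow("EDB1-C2", 36928, None, 64, (640, 640, 64)),
    _PrintedRow("E-Bneck-1", 8256, 128, 64, (640, 640, 64)),
    _PrintedRow("EDB2-C1", 73856, 256, 128, (320, 320, 128)),
    _PrintedRow("EDB2-C2", 147584, None, 128, (320, 320, 128)),
    _PrintedRow(
        "E-Bneck-2", 8256, 128, 64, (640, 640, 64),
        typo="printed row duplicates E-Bneck-1; neighbouring cells force a "
             "256->128 bottleneck: reconciled to 32,896 + 256, output 320x320x128",
    ),
    _PrintedRow("EDB3-C1", 295168, 512, 256, (160, 160, 256)),
    _PrintedRow("EDB3-C2", 590080, None, 256, (160, 160, 256)),
    _PrintedRow("E-Bneck-3", 131328, 512, 64, (160, 160, 256)),
    _PrintedRow("DDB3-C1", 590080, 512, 256, (160, 160, 128)),
    _PrintedRow(
        "DDB3-C2", 295040, None, 64, (160, 160, 640),
        typo="printed filters cell reads 64; the parameter cell 295,040 and "
             "the concat depth 640 = 256+128+256 force 128 filters",
    ),
    _PrintedRow("D-Bneck-1", 82048, 256, 128, (160, 160, 128)),
    _PrintedRow("DDB2-C1", 147584, 256, 128, (320, 320, 64), printed_label="EDB2-C1"),
    _PrintedRow("DDB2-C2", 73792, None, 64, (320, 320, 128), printed_label="EDB2-C2"),
    _PrintedRow("D-Bneck-2", 20544, 128, 64, (320, 320, 64)),
    _PrintedRow("DDB1-C1", 36928, 128, 64, (640, 640, 64)),
    _PrintedRow("DDB1-C2", 1154, None, 2, (640, 640, 2)),
    _PrintedRow("D-Bneck-3", 262, 4, 2, (640, 640, 2)),
)


@dataclass(frozen=True)
class AuditEntry:
    """Comparison of one computed layer against its printed reference row."""

    layer: str
    computed_conv: int
    printed_conv: int
    computed_bn: Optional[int]
    printed_bn: Optional[int]
    computed_output: TensorShape
    printed_output: tuple[int, int, int]
    status: str  # MATCH | RECONCILED | MISMATCH
    note: str = ""


def audit_against_reference(audit: ParamAudit) -> list[AuditEntry]:
    """Compare a computed audit of the canonical graph with the printed table.

    Rows whose printed parameter/filter cells are known to be
    typographical are flagged ``RECONCILED`` with the reconciled count
    reported alongside the printed one; they are never silently altered.
    An audit of an empty graph yields an empty report.
    """
    entries = []
    for row in _TABLE_REFERENCE:
        if row.layer not in audit:
            continue
        rec = audit.record(row.layer)
        bn_name = f"{row.layer}-bn"
        computed_bn = audit.record(bn_name).bn_params if bn_name in audit else None
        notes = []
        if row.typo is not None:
            status = "RECONCILED"
            notes.append(row.typo)
        elif rec.conv_params == row.printed_conv and (
            row.printed_bn is None or computed_bn == row.printed_bn
        ):
            status = "MATCH"
        else:
            status = "MISMATCH"
        if row.printed_label is not None:
            notes.append(f"printed with label {row.printed_label!r} (evident label typo)")
        out = rec.output_shape
        if (out.height, out.width, out.channels) != row.printed_output and status == "MATCH":
            ph, pw, pc = row.printed_output
            notes.append(
                f"printed output cell {ph}x{pw}x{pc} is inconsistent with this row's "
                f"own filter count; computed {out}"
            )
        entries.append(
            AuditEntry(
                layer=row.layer,
                computed_conv=rec.conv_params,
                printed_conv=row.printed_conv,
                computed_bn=computed_bn,
                printed_bn=row.printed_bn,
                computed_output=out,
                printed_output=row.printed_output,
                status=status,
                note="; ".join(notes),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

def format_audit(audit: ParamAudit, graph: NetworkGraph) -> str:
    """Plain-text per-layer summary: name, kind, kernel, in/out channels, shape, params."""
    shapes = propagate_shapes(graph)
    lines = [
        f"{'layer':<18} {'kind':<22} {'kernel':<8} {'in->out':<10} {'output':<14} {'params':>10}",
        "-" * 86,
    ]
    for rec in audit.records:
        spec = graph.layer(rec.name)
        kern = "x".join(map(str, spec.kernel)) if spec.kernel else "-"
        cin = shapes[spec.inputs[0]].channels
        io = f"{cin}->{rec.output_shape.channels}" if spec.kind == "convolution" else "-"
        lines.append(
            f"{rec.name:<18} {rec.kind:<22} {kern:<8} {io:<10} {str(rec.output_shape):<14} {rec.total:>10,}"
        )
    lines.append("-" * 86)
    lines.append(f"{'total':<76} {audit.total:>10,}")
    return "\n".join(lines)


def format_audit_report(entries: Sequence[AuditEntry]) -> str:
    """Plain-text MATCH/RECONCILED report against the printed reference table."""
    lines = [
        f"{'layer':<12} {'computed':>10} {'printed':>10} {'bn':>8} {'status':<12} note",
        "-" * 100,
    ]
    for e in entries:
        bn = f"{e.computed_bn}" if e.computed_bn is not None else "-"
        lines.append(
            f"{e.layer:<12} {e.computed_conv:>10,} {e.printed_conv:>10,} {bn:>8} {e.status:<12} {e.note}"
        )
    n_match = sum(e.status == "MATCH" for e in entries)
    n_rec = sum(e.status == "RECONCILED" for e in entries)
    n_mis = sum(e.status == "MISMATCH" for e in entries)
    lines.append("-" * 100)
    lines.append(f"{n_match} MATCH, {n_rec} RECONCILED, {n_mis} MISMATCH")
    return "\n".join(lines)


def graph_to_json(graph: NetworkGraph) -> str:
    """Serialise a graph to a machine-readable JSON description."""
    payload = {
        "input_shape": [graph.input_shape.height, graph.input_shape.width, graph.input_shape.channels],
        "class_count": graph.class_count,
        "layers": [
            {
                "name": s.name,
                "kind": s.kind,
                "inputs": list(s.inputs),
                "kernel": list(s.kernel) if s.kernel else None,
                "stride": list(s.stride) if s.stride else None,
                "filters": s.filters,
                "partner": s.partner,
            }
            for s in graph
        ],
    }
    return json.dumps(payload, indent=1)


def graph_from_json(text: str) -> NetworkGraph:
    payload = json.loads(text)
    layers = [
        LayerSpec(
            name=d["name"],
            kind=d["kind"],
            inputs=tuple(d["inputs"]),
            kernel=tuple(d["kernel"]) if d["kernel"] else None,
            stride=tuple(d["stride"]) if d["stride"] else None,
            filters=d["filters"],
            partner=d["partner"],
        )
        for d in payload["layers"]
    ]
    h, w, c = payload["input_shape"]
    return NetworkGraph(layers=layers, input_shape=TensorShape(h, w, c), class_count=payload["class_count"])
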