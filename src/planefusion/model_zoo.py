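"""Construction and introspection of the two residual CNN architectures.

The package's feature extractors are two hand-designed residual
convolutional networks — one with three residual merge points, one with
four — each ending in a global-average-pooling (GAP) layer that emits a
2048-wide feature vector per image.  Architectures are represented as
explicit, serializable layer graphs (:class:`ModelGraph`) rather than
opaque framework objects so that shape inference, parameter accounting
and JSON round-tripping are first-class operations.

Conventions
-----------
* All convolutions are 3x3 with biases unless inserted as 1x1 shortcut
  projections; "same"-style padding throughout, with ceil division of
  spatial dims under stride 2 (the only convention under which the deep
  stride-2 stacks keep positive spatial extent down to GAP).
* A pair of consecutive ReLUs is recorded once (ReLU is idempotent).
* The three-residual-block model carries no batch normalization; the
  four-residual-block model has one batchnorm per residual block.
* ``width_scale`` scales every channel width uniformly (minimum 1); the
  default 1.0 reproduces the published widths, including the 2048-wide
  GAP output.  Scaled-down builds share the exact topology and are used
  for desk-scale training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

__all__ = [
    "LayerSpec",
    "ModelGraph",
    "ShapeReport",
    "GraphError",
    "ConfigurationError",
    "build_three_residual_model",
    "build_four_residual_model",
    "infer_shapes",
    "serialize_graph",
    "deserialize_graph",
]

LAYER_KINDS = {
    "input",
    "conv",
    "relu",
    "maxpool",
    "batchnorm",
    "add",
    "gap",
    "fc",
    "softmax",
}


class GraphError(ValueError):
    """Structural problem in a model graph (bad wiring, shape mismatch)."""


class ConfigurationError(ValueError):
    """Invalid builder / layer configuration."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a model graph.

    ``depth`` is the filter / unit count (conv and fc only), ``kernel``
    the spatial extent in pixels (conv and maxpool only), ``stride`` the
    step in pixels.  ``padding_mode`` is ``"same"`` (spatial size divided
    by stride, ceil) or ``"valid"``.
    """

    name: str
    kind: str
    depth: int | None = None
    kernel: int | None = None
    stride: int | None = None
    padding_mode: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ConfigurationError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "fc"):
            if self.depth is None or self.depth < 1:
                raise ConfigurationError(
                    f"layer {self.name!r}: {self.kind} needs depth >= 1, got {self.depth}"
                )
        if self.kind in ("conv", "maxpool"):
            if self.kernel is None or self.kernel < 1:
                raise ConfigurationError(
                    f"layer {self.name!r}: {self.kind} needs kernel >= 1, got {self.kernel}"
                )
            if self.stride is None or self.stride < 1:
                raise ConfigurationError(
                    f"layer {self.name!r}: {self.kind} needs stride >= 1, got {self.stride}"
                )


@dataclass
class ModelGraph:
    """An ordered layer-descriptor DAG with explicit (skip) edges."""

    layers: list[LayerSpec]
    edges: list[tuple[str, str]]
    num_classes: int
    input_shape: tuple[int, int, int]

    def layer(self, name: str) -> LayerSpec:
        for spec in self.layers:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def predecessors(self, name: str) -> list[str]:
        return [src for src, dst in self.edges if dst == name]

    def successors(self, name: str) -> list[str]:
        return [dst for src, dst in self.edges if src == name]

    def topological_order(self) -> list[str]:
        indeg = {spec.name: 0 for spec in self.layers}
        for _, dst in self.edges:
            indeg[dst] += 1
        ready = [n for n, d in indeg.items() if d == 0]
        order: list[str] = []
        while ready:
            node = ready.pop(0)
            order.append(node)
            for nxt in self.successors(node):
                indeg[nxt] -= 1
                if indeg[nxt] == 0:
                    ready.append(nxt)
        if len(order) != len(self.layers):
            raise GraphError("graph contains a cycle")
        return order

    def validate(self) -> None:
        names = [spec.name for spec in self.layers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GraphError(f"duplicate layer names: {dupes}")
        name_set = set(names)
        for src, dst in self.edges:
            if src not in name_set or dst not in name_set:
                raise GraphError(f"edge ({src!r}, {dst!r}) references unknown layer")
        for spec in self.layers:
            n_in = len(self.predecessors(spec.name))
            if spec.kind == "input":
                if n_in != 0:
                    raise GraphError(f"input layer {spec.name!r} has inbound edges")
            elif spec.kind == "add":
                if n_in != 2:
                    raise GraphError(
                        f"add layer {spec.name!r} has {n_in} inbound edges, needs exactly 2"
                    )
            elif n_in != 1:
                raise GraphError(
                    f"layer {spec.name!r} has {n_in} inbound edges, needs exactly 1"
                )
        order = self.topological_order()  # raises on cycle
        # every path from input must terminate at a softmax sink
        sinks = [n for n in order if not self.successors(n)]
        for sink in sinks:
            if self.layer(sink).kind != "softmax":
                raise GraphError(f"terminal layer {sink!r} is not softmax")
        if not sinks:
            raise GraphError("graph has no terminal layer")


@dataclass
class ShapeReport:
    """Per-layer output shapes plus learnable-parameter accounting."""

    shapes: dict[str, tuple[int, int, int]]
    param_counts: dict[str, int]
    total_params: int
    gap_width: int


def _same_out(size: int, stride: int) -> int:
    return max(1, math.ceil(size / stride))


def _valid_out(size: int, kernel: int, stride: int) -> int:
    return (size - kernel) // stride + 1


def infer_shapes(graph: ModelGraph) -> ShapeReport:
    """Run shape inference over a graph.

    Returns per-layer output shapes ``(h, w, c)`` (fc/softmax use
    ``(1, 1, units)``), learnable parameter counts (conv:
    ``k^2 * c_in * depth + depth``; batchnorm: ``2 * c``; fc:
    ``c_in * depth + depth``; everything else 0) and the channel width
    at the GAP output.

    Raises :class:`GraphError` when the two inputs of an add layer
    disagree (a mis-specified shortcut) or a spatial dimension collapses
    below one pixel.
    """

    graph.validate()
    shapes: dict[str, tuple[int, int, int]] = {}
    params: dict[str, int] = {}
    gap_width = 0
    for name in graph.topological_order():
        spec = graph.layer(name)
        preds = graph.predecessors(name)
        params[name] = 0
        if spec.kind == "input":
            shapes[name] = graph.input_shape
            continue
        in_shapes = [shapes[p] for p in preds]
        h, w, c = in_shapes[0]
        if spec.kind == "conv":
            if spec.padding_mode == "valid":
                oh, ow = _valid_out(h, spec.kernel, spec.stride), _valid_out(
                    w, spec.kernel, spec.stride
                )
            else:
                oh, ow = _same_out(h, spec.stride), _same_out(w, spec.stride)
            if oh < 1 or ow < 1:
                raise GraphError(
                    f"layer {name!r}: spatial dimension collapses to {oh}x{ow}"
                )
            shapes[name] = (oh, ow, spec.depth)
            params[name] = spec.kernel**2 * c * spec.depth + spec.depth
        elif spec.kind == "maxpool":
            if spec.padding_mode == "valid":
                oh, ow = _valid_out(h, spec.kernel, spec.stride), _valid_out(
                    w, spec.kernel, spec.stride
                )
            else:
                oh, ow = _same_out(h, spec.stride), _same_out(w, spec.stride)
            if oh < 1 or ow < 1:
                raise GraphError(
                    f"layer {name!r}: spatial dimension collapses to {oh}x{ow}"
                )
            shapes[name] = (oh, ow, c)
        elif spec.kind == "batchnorm":
            shapes[name] = (h, w, c)
            params[name] = 2 * c
        elif spec.kind in ("relu",):
            shapes[name] = (h, w, c)
        elif spec.kind == "add":
            a, b = in_shapes
            if a != b:
                raise GraphError(
                    f"add layer {name!r}: inbound shapes {a} and {b} differ "
                    "(mis-specified shortcut)"
                )
            shapes[name] = a
        elif spec.kind == "gap":
            shapes[name] = (1, 1, c)
            gap_width = c
        elif spec.kind == "fc":
            shapes[name] = (1, 1, spec.depth)
            params[name] = c * spec.depth + spec.depth
        elif spec.kind == "softmax":
            shapes[name] = (h, w, c)
    total = int(sum(params.values()))
    return ShapeReport(shapes=shapes, param_counts=params, total_params=total, gap_width=gap_width)


class _Builder:
    """Sequential graph assembly helper with taps for skip connections."""

    def __init__(self, input_shape: tuple[int, int, int], num_classes: int):
        self.layers: list[LayerSpec] = [LayerSpec("input", "input")]
        self.edges: list[tuple[str, str]] = []
        self.tail = "input"
        self.num_classes = num_classes
        self.input_shape = input_shape
        self._channels: dict[str, int] = {"input": input_shape[2]}

    def _append(self, spec: LayerSpec, channels: int, src: str | None = None) -> str:
        self.layers.append(spec)
        self.edges.append((src or self.tail, spec.name))
        self.tail = spec.name
        self._channels[spec.name] = channels
        return spec.name

    def conv(self, name: str, depth: int, stride: int = 1, kernel: int = 3) -> str:
        return self._append(
            LayerSpec(name, "conv", depth=depth, kernel=kernel, stride=stride, padding_mode="same"),
            depth,
        )

    def relu(self, name: str) -> str:
        return self._append(LayerSpec(name, "relu"), self._channels[self.tail])

    def maxpool(self, name: str, kernel: int = 3, stride: int = 1) -> str:
        return self._append(
            LayerSpec(name, "maxpool", kernel=kernel, stride=stride, padding_mode="same"),
            self._channels[self.tail],
        )

    def batchnorm(self, name: str) -> str:
        return self._append(LayerSpec(name, "batchnorm"), self._channels[self.tail])

    def add(self, name: str, other: str) -> str:
        """Merge ``tail`` with ``other``; insert a 1x1 projection on the
        shortcut path when the channel widths disagree."""
        main_c = self._channels[self.tail]
        short_c = self._channels[other]
        if short_c != main_c:
            proj = LayerSpec(
                f"{name}_proj", "conv", depth=main_c, kernel=1, stride=1, padding_mode="same"
            )
            self.layers.append(proj)
            self.edges.append((other, proj.name))
            self._channels[proj.name] = main_c
            other = proj.name
        spec = LayerSpec(name, "add")
        self.layers.append(spec)
        self.edges.append((self.tail, name))
        self.edges.append((other, name))
        self.tail = name
        self._channels[name] = main_c
        return name

    def head(self) -> None:
        self._append(LayerSpec("gap", "gap"), self._channels[self.tail])
        self._append(
            LayerSpec("fc", "fc", depth=self.num_classes), self.num_classes
        )
        self._append(LayerSpec("softmax", "softmax"), self.num_classes)

    def build(self) -> ModelGraph:
        graph = ModelGraph(
            layers=self.layers,
            edges=self.edges,
            num_classes=self.num_classes,
            input_shape=self.input_shape,
        )
        graph.validate()
        return graph


def _check_input(num_classes: int, input_shape: Sequence[int]) -> tuple[int, int, int]:
    if num_classes < 2:
        raise ConfigurationError(f"num_classes must be >= 2, got {num_classes}")
    shape = tuple(int(v) for v in input_shape)
    if len(shape) != 3:
        raise ConfigurationError(f"input_shape must be (h, w, c), got {shape}")
    for axis, size in zip(("height", "width"), shape[:2]):
        if size < 32:
            raise ConfigurationError(
                f"input {axis} {size} is below the minimum of 32: the stride-2 "
                "stack would collapse the feature map before global pooling"
            )
    if shape[2] < 1:
        raise ConfigurationError(f"input channels must be >= 1, got {shape[2]}")
    return shape


def _scaled(depth: int, width_scale: float) -> int:
    return max(1, round(depth * width_scale))


def build_three_residual_model(
    num_classes: int,
    input_shape: Sequence[int] = (224, 224, 3),
    width_scale: float = 1.0,
) -> ModelGraph:
    """Build the three-residual-block CNN.

    The trunk downsamples with stride-2 3x3 convolutions; three residual
    blocks (all internal strides 1) merge through add layers; the head is
    GAP -> fc(num_classes) -> softmax with a 2048-wide GAP output at the
    default ``width_scale``.
    """

    shape = _check_input(num_classes, input_shape)
    d = lambda depth: _scaled(depth, width_scale)
    b = _Builder(shape, num_classes)

    # stem
    b.conv("conv1", d(32), stride=2)
    b.relu("relu1")
    b.conv("conv2", d(64), stride=2)
    b.relu("relu2")
    tap1 = b.maxpool("pool1")

    # residual block 1: two 512-deep convs then a 64-deep conv, all stride 1
    b.conv("rb1_conv1", d(512))
    b.relu("rb1_relu1")
    b.conv("rb1_conv2", d(512))
    b.relu("rb1_relu2")
    b.conv("rb1_conv3", d(64))
    b.add("add1", tap1)

    # trunk to block 2
    b.conv("t2_conv1", d(1024), stride=2)
    b.relu("t2_relu1")
    b.conv("t2_conv2", d(1024), stride=2)
    b.relu("t2_relu2")
    b.maxpool("pool2")
    b.conv("t2_conv3", d(512), stride=2)
    b.conv("t2_conv4", d(64), stride=2)
    b.maxpool("pool3")
    b.conv("t2_conv5", d(1024), stride=2)
    tap2 = b.relu("t2_relu3")

    # residual block 2
    b.conv("rb2_conv1", d(64))
    b.relu("rb2_relu1")
    b.conv("rb2_conv2", d(512))
    b.relu("rb2_relu2")
    b.conv("rb2_conv3", d(512))
    b.relu("rb2_relu3")
    b.maxpool("rb2_pool")
    b.conv("rb2_conv4", d(512))
    b.conv("rb2_conv5", d(1024))
    b.add("add2", tap2)

    # trunk to block 3
    b.conv("t3_conv1", d(512), stride=2)
    b.relu("t3_relu1")
    b.conv("t3_conv2", d(512), stride=2)
    b.relu("t3_relu2")
    b.conv("t3_conv3", d(1024), stride=2)
    b.relu("t3_relu3")
    b.conv("t3_conv4", d(1024), stride=2)
    b.relu("t3_relu4")
    b.maxpool("pool4")
    b.conv("t3_conv5", d(2048), stride=2)
    b.relu("t3_relu5")
    tap3 = b.maxpool("pool5")

    # residual block 3
    b.conv("rb3_conv1", d(64))
    b.relu("rb3_relu1")
    b.conv("rb3_conv2", d(1024))
    b.relu("rb3_relu2")
    b.maxpool("rb3_pool")
    b.conv("rb3_conv3", d(1024))
    b.relu("rb3_relu3")
    b.conv("rb3_conv4", d(2048))
    b.add("add3", tap3)

    # head
    b.conv("h_conv1", d(2048), stride=2)
    b.relu("h_relu1")
    b.conv("h_conv2", d(2048), stride=2)
    b.relu("h_relu2")
    b.head()
    return b.build()


def build_four_residual_model(
    num_classes: int,
    input_shape: Sequence[int] = (224, 224, 3),
    width_scale: float = 1.0,
) -> ModelGraph:
    """Build the four-residual-block CNN.

    Same conventions as :func:`build_three_residual_model` but with four
    residual merges, one batch-normalization layer per residual block,
    and a max-pool closing each block.
    """

    shape = _check_input(num_classes, input_shape)
    d = lambda depth: _scaled(depth, width_scale)
    b = _Builder(shape, num_classes)

    # stem
    b.conv("conv1", d(64), stride=2)
    b.relu("relu1")
    b.conv("conv2", d(256), stride=2)
    b.relu("relu2")
    tap1 = b.maxpool("pool1")

    # residual block 1 (batchnorm at 256 channels)
    b.conv("rb1_conv1", d(64))
    b.relu("rb1_relu1")
    b.conv("rb1_conv2", d(256))
    b.relu("rb1_relu2")
    b.batchnorm("rb1_bn")
    b.maxpool("rb1_pool")
    b.add("add1", tap1)

    # trunk to block 2
    b.conv("t2_conv1", d(64), stride=2)
    b.relu("t2_relu1")
    b.conv("t2_conv2", d(256), stride=2)
    b.relu("t2_relu2")
    b.conv("t2_conv3", d(512), stride=2)
    b.relu("t2_relu3")
    b.conv("t2_conv4", d(1024), stride=2)
    b.relu("t2_relu4")
    tap2 = b.maxpool("pool2")

    # residual block 2 (batchnorm at 1024 channels)
    b.conv("rb2_conv1", d(512))
    b.relu("rb2_relu1")
    b.conv("rb2_conv2", d(1024))
    b.relu("rb2_relu2")
    b.batchnorm("rb2_bn")
    b.maxpool("rb2_pool")
    b.add("add2", tap2)

    # trunk to block 3
    b.conv("t3_conv1", d(512), stride=2)
    b.relu("t3_relu1")
    b.conv("t3_conv2", d(1024), stride=2)
    b.relu("t3_relu2")
    b.conv("t3_conv3", d(2048), stride=2)
    b.relu("t3_relu3")
    tap3 = b.maxpool("pool3")

    # residual block 3 (batchnorm at 2048 channels)
    b.conv("rb3_conv1", d(1024))
    b.relu("rb3_relu1")
    b.conv("rb3_conv2", d(2048))
    b.relu("rb3_relu2")
    b.batchnorm("rb3_bn")
    b.maxpool("rb3_pool")
    tap4 = b.add("add3", tap3)

    # residual block 4 follows immediately (batchnorm at 2048 channels)
    b.conv("rb4_conv1", d(1024))
    b.relu("rb4_relu1")
    b.conv("rb4_conv2", d(2048))
    b.relu("rb4_relu2")
    b.batchnorm("rb4_bn")
    b.maxpool("rb4_pool")
    b.add("add4", tap4)

    # head
    b.conv("h_conv1", d(1024), stride=2)
    b.relu("h_relu1")
    b.conv("h_conv2", d(2048))
    b.relu("h_relu2")
    b.maxpool("h_pool")
    b.head()
    return b.build()


# ---------------------------------------------------------------------------
# JSON serialization


def serialize_graph(graph: ModelGraph) -> str:
    """Serialize a graph to a JSON document (round-trip safe)."""
    graph.validate()
    doc = {
        "input_shape": list(graph.input_shape),
        "num_classes": graph.num_classes,
        "layers": [
            {k: v for k, v in asdict(spec).items() if v is not None}
            for spec in graph.layers
        ],
        "edges": [[src, dst] for src, dst in graph.edges],
    }
    return json.dumps(doc, indent=1)


def deserialize_graph(doc: str | dict) -> ModelGraph:
    """Parse a JSON document back into a validated :class:`ModelGraph`."""
    if isinstance(doc, str):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise GraphError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise GraphError("document root must be an object")
    for key in ("input_shape", "num_classes", "layers", "edges"):
        if key not in doc:
            raise GraphError(f"document missing required field {key!r}")
    layers = []
    for i, entry in enumerate(doc["layers"]):
        if "name" not in entry or "kind" not in entry:
            raise GraphError(f"layers[{i}] missing 'name' or 'kind'")
        try:
            layers.append(LayerSpec(**entry))
        except (TypeError, ConfigurationError) as exc:
            raise GraphError(f"layers[{i}]: {exc}") from exc
    edges = []
    for i, pair in enumerate(doc["edges"]):
        if not isinstance(pair, (list, tuple)) or len(pair) != 2:
            raise GraphError(f"edges[{i}] must be a [src, dst] pair")
        edges.append((pair[0], pair[1]))
    graph = ModelGraph(
        layers=layers,
        edges=edges,
        num_classes=int(doc["num_classes"]),
        input_shape=tuple(int(v) for v in doc["input_shape"]),
    )
    graph.validate()
    return graph
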