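"""Layer-graph descriptions of the RefineNet and atrous DenseNet (ADN) classifiers.

A :class:`ModelGraph` is an explicit, inspectable DAG of :class:`LayerSpec`
nodes (sequential edges plus dense concatenation edges) over which channel and
spatial-shape arithmetic can be asserted *before* any weights exist.  The
numpy training backend (:mod:`patchrefine.nn`) compiles these graphs into
trainable networks.

Two architectures are provided:

* **RefineNet** -- a small six-convolution CNN (plus two fully connected
  layers) used inside the reverse-active-learning loop to score patch
  confidence.
* **ADN** (atrous DenseNet) -- a wide, shallow DenseNet variant whose dense
  blocks (ADC modules) pair an atrous 3x3 convolution (dilation alternating
  between 2 and 3) with a fusing 3x3 convolution, followed by a
  network-in-network (1x1 convolution) head.  The reference configuration has
  28 weighted layers and per-module growth rates 8, 16 and 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

__all__ = [
    "LayerSpec",
    "ModelGraph",
    "ADCConfig",
    "ADNConfig",
    "ShapeError",
    "effective_kernel_extent",
    "dense_input_channels",
    "build_refinenet",
    "build_adc_module",
    "build_adn",
    "reference_adn",
    "count_weighted_layers",
    "parameter_count",
    "describe",
    "WEIGHTED_KINDS",
]

#: layer kinds carrying trainable kernels
WEIGHTED_KINDS = frozenset({"conv", "atrous_conv", "nin_conv1x1", "fully_connected"})

_KINDS = frozenset(
    {
        "input",
        "conv",
        "atrous_conv",
        "max_pool",
        "avg_pool",
        "global_avg_pool",
        "fully_connected",
        "concat",
        "nin_conv1x1",
        "activation",
        "batch_norm",
    }
)


class ShapeError(ValueError):
    """Raised when forward-shape inference fails; carries the partial trace."""

    def __init__(self, message: str, trace: Optional[list] = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class LayerSpec:
    """One node of a model graph.

    ``dilation >= 2`` is only legal for ``atrous_conv``; a plain ``conv``
    always has ``dilation == 1`` (a common convolution is the special case of
    an atrous convolution with dilation rate 1).
    """

    kind: str
    kernel: Optional[int] = None
    dilation: int = 1
    out_channels: Optional[int] = None
    stride: int = 1
    inputs: List[int] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.dilation >= 2 and self.kind != "atrous_conv":
            raise ValueError("dilation >= 2 requires kind='atrous_conv'")
        if self.kind == "conv" and self.dilation != 1:
            raise ValueError("a common conv has dilation 1")
        if self.kind == "atrous_conv" and self.dilation < 2:
            raise ValueError("atrous_conv requires dilation >= 2")


class ModelGraph:
    """An ordered layer list with explicit connectivity.

    Node 0 is always the pseudo-node ``input``.  Convolutions are stride-1
    with 'same' zero padding (spatial downsampling is done by pooling nodes),
    which keeps the dense concatenations spatially consistent.
    """

    def __init__(self, input_size: Tuple[int, int, int]):
        h, w, c = input_size
        self.input_size = (int(h), int(w), int(c))
        self.layers: List[LayerSpec] = [
            LayerSpec(kind="input", out_channels=int(c), name="input")
        ]

    def add(self, kind: str, *, inputs: Optional[Sequence[int]] = None, **kw) -> int:
        """Append a node; defaults to consuming the previous node's output."""
        if inputs is None:
            inputs = [len(self.layers) - 1]
        spec = LayerSpec(kind=kind, inputs=list(inputs), **kw)
        for i in spec.inputs:
            if not (0 <= i < len(self.layers)):
                raise ValueError(f"node input index {i} out of range")
        self.layers.append(spec)
        return len(self.layers) - 1

    # -- shape inference -------------------------------------------------

    def shapes(self) -> List[Tuple[int, int, int]]:
        """Per-node output shapes (H, W, C); C-only nodes use H = W = 1.

        Raises :class:`ShapeError` with the partial trace on inconsistency.
        """
        out: List[Tuple[int, int, int]] = []
        for idx, spec in enumerate(self.layers):
            try:
                out.append(self._node_shape(idx, spec, out))
            except ShapeError:
                raise
            except Exception as exc:  # re-wrap with trace
                raise ShapeError(f"node {idx} ({spec.kind}): {exc}", trace=out) from exc
        return out

    def _node_shape(self, idx, spec, done):
        k = spec.kind
        if k == "input":
            h, w, c = self.input_size
            return (h, w, c)
        ins = [done[i] for i in spec.inputs]
        if k in ("conv", "atrous_conv", "nin_conv1x1"):
            (h, w, c) = ins[0]
            return (h, w, spec.out_channels)
        if k == "max_pool":
            (h, w, c) = ins[0]
            s = spec.kernel
            if h < s or w < s:
                raise ShapeError(
                    f"node {idx}: {s}x{s} pool does not fit {h}x{w} map", trace=done
                )
            return (h // s, w // s, c)
        if k == "avg_pool":
            (h, w, c) = ins[0]
            s = spec.kernel
            if h < s or w < s:
                raise ShapeError(
                    f"node {idx}: {s}x{s} avg pool does not fit {h}x{w} map",
                    trace=done,
                )
            return (h // s, w // s, c)
        if k == "global_avg_pool":
            (h, w, c) = ins[0]
            return (1, 1, c)
        if k == "fully_connected":
            return (1, 1, spec.out_channels)
        if k == "concat":
            h, w, _ = ins[0]
            for (h2, w2, _) in ins[1:]:
                if (h2, w2) != (h, w):
                    raise ShapeError(
                        f"node {idx}: concat of mismatched spatial sizes", trace=done
                    )
            return (h, w, sum(s[2] for s in ins))
        if k in ("activation", "batch_norm"):
            return ins[0]
        raise ShapeError(f"node {idx}: unhandled kind {k}", trace=done)

    def in_channels(self, idx: int, shapes=None) -> int:
        shapes = shapes if shapes is not None else self.shapes()
        spec = self.layers[idx]
        if spec.kind == "fully_connected":
            h, w, c = shapes[spec.inputs[0]]
            return h * w * c
        return sum(shapes[i][2] for i in spec.inputs)

    def __len__(self):
        return len(self.layers)


# -- channel / receptive-field arithmetic --------------------------------


def effective_kernel_extent(kernel: int, dilation: int) -> int:
    """Spatial extent of a dilated kernel: ``kernel + (kernel-1)(dilation-1)``.

    Inserting ``dilation - 1`` holes between adjacent taps enlarges the
    receptive field without adding parameters; dilation 1 recovers the common
    convolution.
    """
    if kernel < 1 or dilation < 1:
        raise ValueError("kernel and dilation must be >= 1")
    return kernel + (kernel - 1) * (dilation - 1)


def dense_input_channels(k0: int, k: int, l: int) -> int:
    """Input channels of dense layer ``l`` (1-based): ``k0 + k*(l-1)``.

    ``k0`` is the block input width and ``k`` the growth rate: each dense
    layer appends k feature maps to the running concatenation.
    """
    if l < 1:
        raise ValueError("dense layer index l is 1-based")
    return k0 + k * (l - 1)


# -- RefineNet -----------------------------------------------------------

#: (kind, kernel, out_channels) for the 14 pipeline stages of RefineNet.
#: The average-pool kernel (stage 12) equals input_side / 32 (7 for 224x224).
_REFINENET_STAGES = [
    ("conv", 3, 16),
    ("max_pool", 2, None),
    ("conv", 3, 32),
    ("max_pool", 2, None),
    ("conv", 3, 64),
    ("max_pool", 2, None),
    ("conv", 3, 64),
    ("max_pool", 2, None),
    ("conv", 3, 128),
    ("max_pool", 2, None),
    ("conv", 3, 128),
    ("avg_pool", None, None),
    ("fully_connected", None, 256),
    ("fully_connected", None, None),
]


def build_refinenet(
    n_classes: int, input_size: Tuple[int, int] = (224, 224)
) -> ModelGraph:
    """Six-convolution confidence-scoring CNN.

    Pipeline: C3x3,16 - MP2 - C3x3,32 - MP2 - C3x3,64 - MP2 - C3x3,64 - MP2 -
    C3x3,128 - MP2 - C3x3,128 - AP - FC256 - FC n_classes.  The closing
    average pool consumes the whole remaining map, so the input side must be a
    multiple of 32 (224 gives the reference 7x7 average pool); anything else
    raises :class:`ShapeError` carrying the computed shape trace.
    """
    h, w = input_size
    if h != w or h % 32 != 0 or h < 32:
        # compute the trace up to the failure for the diagnostic
        g = ModelGraph((h, w, 3))
        trace = [(h, w, 3)]
        hh, ww = h, w
        for kind, kernel, cc in _REFINENET_STAGES[:11]:
            if kind == "max_pool":
                if hh < 2 or ww < 2:
                    break
                hh, ww = hh // 2, ww // 2
            trace.append((hh, ww, cc))
        raise ShapeError(
            f"RefineNet needs a square input with side a positive multiple of 32; "
            f"got {h}x{w} (final average pool cannot consume a {hh}x{ww} map)",
            trace=trace,
        )
    ap = h // 32
    g = ModelGraph((h, w, 3))
    for kind, kernel, cc in _REFINENET_STAGES:
        if kind == "conv":
            g.add("conv", kernel=kernel, out_channels=cc)
        elif kind == "max_pool":
            g.add("max_pool", kernel=2, stride=2)
        elif kind == "avg_pool":
            g.add("avg_pool", kernel=ap, stride=ap)
        else:  # fully_connected
            g.add("fully_connected", out_channels=cc if cc else n_classes)
    g.shapes()  # validate
    return g


# -- ADN -----------------------------------------------------------------


@dataclass
class ADCConfig:
    """One atrous-dense-connection block.

    Each of the ``n_dense_layers`` dense layers is an atrous 3x3 convolution
    (dilation drawn cyclically from ``dilations``) followed by a common 3x3
    convolution that fuses the multiscale features; both emit ``growth_rate``
    maps, and the fused output joins the running concatenation.
    """

    n_dense_layers: int = 4
    growth_rate: int = 8
    dilations: Tuple[int, ...] = (2, 3)
    input_channels: Optional[int] = None  # inferred at build time if None

    def __post_init__(self):
        if not self.dilations or any(d not in (2, 3) for d in self.dilations):
            raise ValueError("dilations must be a non-empty sequence over {2, 3}")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if self.n_dense_layers < 1:
            raise ValueError("need at least one dense layer")


@dataclass
class ADNConfig:
    """Full atrous DenseNet: stem, three ADC modules, NIN head, FC softmax.

    The reference configuration (stem conv; 3 modules x 4 dense layers x
    2 convs; two 1x1 NIN convs; one FC head) totals 28 weighted layers.
    """

    n_classes: int = 4
    input_size: Tuple[int, int] = (64, 64)
    stem_channels: int = 16
    adc_modules: Tuple[ADCConfig, ...] = (
        ADCConfig(growth_rate=8),
        ADCConfig(growth_rate=16),
        ADCConfig(growth_rate=32),
    )
    nin_channels: Tuple[int, ...] = (128, 64)
    strict_reference: bool = False

    def __post_init__(self):
        rates = [m.growth_rate for m in self.adc_modules]
        if any(a >= b for a, b in zip(rates, rates[1:])):
            raise ValueError("growth rates must strictly increase across modules")


def build_adc_module(graph: ModelGraph, input_node: int, config: ADCConfig) -> int:
    """Append one ADC block to ``graph``; returns the output concat node.

    Dense layer ``l`` consumes the concatenation of the module input and all
    previous dense outputs (k0 + k*(l-1) channels); the module output
    concatenates everything, k0 + n_dense_layers*k channels wide.
    """
    feats = [input_node]
    for l in range(config.n_dense_layers):
        src = feats[0] if len(feats) == 1 else graph.add("concat", inputs=list(feats))
        gamma = config.dilations[l % len(config.dilations)]
        at = graph.add(
            "atrous_conv",
            kernel=3,
            dilation=gamma,
            out_channels=config.growth_rate,
            inputs=[src],
            name=f"adc_atrous_l{l + 1}",
        )
        fuse = graph.add(
            "conv",
            kernel=3,
            out_channels=config.growth_rate,
            inputs=[at],
            name=f"adc_fuse_l{l + 1}",
        )
        feats.append(fuse)
    return graph.add("concat", inputs=list(feats), name="adc_out")


def build_adn(config: ADNConfig) -> ModelGraph:
    """Stem conv + max-pool, three ADC modules separated by 2x2 average
    pools, NIN 1x1 convolutions, global average pooling and an FC softmax
    head.  Transitions are parameter-free pools so that the weighted-layer
    budget of the reference configuration is exactly 28.
    """
    h, w = config.input_size
    if min(h, w) < 16:
        raise ValueError("ADN input must be at least 16x16")
    g = ModelGraph((h, w, 3))
    node = g.add("conv", kernel=3, out_channels=config.stem_channels, name="stem")
    node = g.add("max_pool", kernel=2, stride=2, inputs=[node])
    for i, m in enumerate(config.adc_modules):
        node = build_adc_module(g, node, m)
        if i < len(config.adc_modules) - 1:
            node = g.add("avg_pool", kernel=2, stride=2, inputs=[node])
    for cc in config.nin_channels:
        node = g.add("nin_conv1x1", kernel=1, out_channels=cc, inputs=[node])
    node = g.add("global_avg_pool", inputs=[node])
    g.add("fully_connected", out_channels=config.n_classes, inputs=[node])
    g.shapes()  # validate
    n = count_weighted_layers(g)
    if config.strict_reference and n != 28:
        raise ValueError(f"reference ADN must have 28 weighted layers, built {n}")
    return g


def reference_adn(n_classes: int = 4, input_size: Tuple[int, int] = (64, 64)) -> ModelGraph:
    """The reference 28-weighted-layer ADN with growth rates 8, 16, 32."""
    return build_adn(
        ADNConfig(n_classes=n_classes, input_size=input_size, strict_reference=True)
    )


# -- graph queries -------------------------------------------------------


def count_weighted_layers(graph: ModelGraph) -> int:
    """Number of layers with trainable kernels (conv, atrous conv, NIN 1x1,
    fully connected); pooling, concat, activation and norm are excluded."""
    return sum(1 for s in graph.layers if s.kind in WEIGHTED_KINDS)


def parameter_count(graph: ModelGraph, idx: int) -> int:
    """Trainable parameters of node ``idx`` (kernel weights + bias).

    Dilation does not enter: an atrous kernel has holes, not extra taps.
    """
    spec = graph.layers[idx]
    if spec.kind not in WEIGHTED_KINDS:
        return 0
    cin = graph.in_channels(idx)
    if spec.kind == "fully_connected":
        return cin * spec.out_channels + spec.out_channels
    return spec.kernel * spec.kernel * cin * spec.out_channels + spec.out_channels


def describe(graph: ModelGraph) -> str:
    """Layer table (kind, kernel, dilation, channels, output shape)."""
    shapes = graph.shapes()
    lines = [f"{'#':>3} {'kind':<16} {'kernel':>6} {'dil':>3} {'ch':>5} {'output':>14}"]
    for i, (spec, shp) in enumerate(zip(graph.layers, shapes)):
        kern = f"{spec.kernel}x{spec.kernel}" if spec.kernel else "-"
        lines.append(
            f"{i:>3} {spec.kind:<16} {kern:>6} {spec.dilation:>3} "
            f"{shp[2]:>5} {f'{shp[0]}x{shp[1]}x{shp[2]}':>14}"
        )
    return "\n".join(lines)
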