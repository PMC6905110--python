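"""Analytic accounting for sequential convolutional architectures.

A network is described as data (:class:`NetworkSpec`), from which everything
else is derived: receptive-field geometry (the r/j/p recursions), output
shapes, multiplication FLOPs and parameter counts, and — in
:mod:`localcount.netcore` — the runnable model itself. Keeping a single
declarative source of truth is what lets the count-map geometry, the training
targets and the network outputs stay aligned by construction.

Geometry recursions (layer ``l`` with kernel ``k``, stride ``s``, padding
``pad``; ``r`` receptive field, ``j`` jump = input-pixel spacing of adjacent
output units, ``p`` accumulated zero padding per border)::

    r_l = r_{l-1} + (k_l - 1) * j_{l-1}
    j_l = j_{l-1} * s_l
    p_l = p_{l-1} + pad_l * j_{l-1}

with ``r_0 = j_0 = 1``, ``p_0 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import yaml

from .errors import GeometryError, ValidationError

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "GeometryReport",
    "CostReport",
    "conv",
    "maxpool",
    "receptive_field",
    "output_shape",
    "count_mult_flops",
    "count_parameters",
    "tasselnetv2_spec",
    "tasselnet_spec",
    "tasselnet_ctx_spec",
    "strip_padding",
    "spec_to_dict",
    "spec_from_dict",
    "dump_spec",
    "load_spec",
]


@dataclass(frozen=True)
class LayerSpec:
    """One convolution or max-pooling layer.

    ``kernel`` is (height, width) in pixels; ``padding`` is symmetric zero
    padding per side; channel fields apply to conv layers only.
    """

    name: str
    kind: str  # "conv" | "maxpool"
    kernel: Tuple[int, int]
    stride: int = 1
    padding: int = 0
    in_channels: Optional[int] = None
    out_channels: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "maxpool"):
            raise ValidationError(f"layer {self.name!r}: unknown kind {self.kind!r}")
        kh, kw = self.kernel
        if kh < 1 or kw < 1:
            raise ValidationError(f"layer {self.name!r}: kernel dims must be >= 1, got {self.kernel}")
        if self.stride < 1:
            raise ValidationError(f"layer {self.name!r}: stride must be >= 1, got {self.stride}")
        if self.padding < 0:
            raise ValidationError(f"layer {self.name!r}: padding must be >= 0, got {self.padding}")
        if self.kind == "conv":
            if not self.in_channels or not self.out_channels:
                raise ValidationError(f"conv layer {self.name!r} needs in_channels and out_channels")
            if self.in_channels < 1 or self.out_channels < 1:
                raise ValidationError(f"layer {self.name!r}: channel counts must be positive")
        elif self.in_channels is not None or self.out_channels is not None:
            raise ValidationError(f"maxpool layer {self.name!r} must not declare channels")

    @property
    def n_parameters(self) -> int:
        """Weight-only learnable parameters (biases and norm stats excluded)."""
        if self.kind != "conv":
            return 0
        kh, kw = self.kernel
        return kh * kw * self.in_channels * self.out_channels


def conv(name: str, kernel: int | Tuple[int, int], cin: int, cout: int,
         stride: int = 1, pad: int = 0) -> LayerSpec:
    if isinstance(kernel, int):
        kernel = (kernel, kernel)
    return LayerSpec(name, "conv", tuple(kernel), stride, pad, cin, cout)


def maxpool(name: str, kernel: int = 2, stride: int = 2) -> LayerSpec:
    return LayerSpec(name, "maxpool", (kernel, kernel), stride, 0)


@dataclass(frozen=True)
class NetworkSpec:
    """An ordered stack of layers plus the input channel count (3 for RGB)."""

    layers: Tuple[LayerSpec, ...]
    input_channels: int = 3
    name: str = "network"

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValidationError("NetworkSpec requires at least one layer")
        if self.input_channels < 1:
            raise ValidationError("input_channels must be positive")
        chans = self.input_channels
        for layer in self.layers:
            if layer.kind == "conv":
                if layer.in_channels != chans:
                    raise ValidationError(
                        f"layer {layer.name!r}: expects {layer.in_channels} input "
                        f"channels but receives {chans}")
                chans = layer.out_channels


@dataclass(frozen=True)
class GeometryRow:
    name: str
    receptive_field: int
    jump: int
    accumulated_padding: int
    spatial_shape: Optional[Tuple[int, int]] = None


@dataclass(frozen=True)
class GeometryReport:
    """Per-layer receptive field / jump / accumulated padding, plus totals."""

    rows: Tuple[GeometryRow, ...]

    @property
    def rf(self) -> int:
        return self.rows[-1].receptive_field

    @property
    def stride(self) -> int:
        return self.rows[-1].jump

    @property
    def padding(self) -> int:
        return self.rows[-1].accumulated_padding

    def to_dict(self) -> dict:
        return {
            "layers": [asdict(r) for r in self.rows],
            "totals": {"rf": self.rf, "stride": self.stride, "padding": self.padding},
        }

    def format_text(self) -> str:
        lines = [f"{'layer':<10}{'rf':>6}{'jump':>6}{'pad':>6}  shape"]
        for r in self.rows:
            shape = "x".join(map(str, r.spatial_shape)) if r.spatial_shape else "-"
            lines.append(f"{r.name:<10}{r.receptive_field:>6}{r.jump:>6}"
                         f"{r.accumulated_padding:>6}  {shape}")
        lines.append(f"total rf={self.rf} stride={self.stride} padding={self.padding}")
        return "\n".join(lines)


@dataclass(frozen=True)
class CostReport:
    """Exact integer multiplication counts and parameter counts per layer."""

    layer_names: Tuple[str, ...]
    multiplications: Tuple[int, ...]
    parameters: Tuple[int, ...]

    @property
    def total_multiplications(self) -> int:
        return sum(self.multiplications)

    @property
    def total_parameters(self) -> int:
        return sum(self.parameters)

    def to_dict(self) -> dict:
        return {
            "layers": [
                {"name": n, "multiplications": m, "parameters": p}
                for n, m, p in zip(self.layer_names, self.multiplications, self.parameters)
            ],
            "total_multiplications": self.total_multiplications,
            "total_parameters": self.total_parameters,
        }

    def format_text(self) -> str:
        lines = [f"{'layer':<10}{'mults':>16}{'params':>12}"]
        for n, m, p in zip(self.layer_names, self.multiplications, self.parameters):
            lines.append(f"{n:<10}{m:>16,}{p:>12,}")
        lines.append(f"{'total':<10}{self.total_multiplications:>16,}"
                     f"{self.total_parameters:>12,}")
        return "\n".join(lines)


def receptive_field(spec: NetworkSpec, input_hw: Optional[Tuple[int, int]] = None) -> GeometryReport:
    """Run the r/j/p recursions over the stack; optionally track spatial shapes."""
    rows = []
    r_h = r_w = 1
    j = 1
    p = 0
    hw = tuple(input_hw) if input_hw is not None else None
    for layer in spec.layers:
        kh, kw = layer.kernel
        r_h = r_h + (kh - 1) * j
        r_w = r_w + (kw - 1) * j
        p = p + layer.padding * j
        j = j * layer.stride
        if hw is not None:
            hw = _shape_through(hw, layer)
        # canonical stacks are square; report the max extent for safety
        rows.append(GeometryRow(layer.name, max(r_h, r_w), j, p, hw))
    return GeometryReport(tuple(rows))


def _shape_through(hw: Tuple[int, int], layer: LayerSpec) -> Tuple[int, int]:
    kh, kw = layer.kernel
    h = (hw[0] + 2 * layer.padding - kh) // layer.stride + 1
    w = (hw[1] + 2 * layer.padding - kw) // layer.stride + 1
    if h < 1 or w < 1:
        raise GeometryError(
            f"input too small: layer {layer.name!r} would produce a "
            f"{h}x{w} output from {hw[0]}x{hw[1]}")
    return (h, w)


def output_shape(spec: NetworkSpec, input_hw: Tuple[int, int]) -> Tuple[int, int]:
    """Spatial output shape (H', W') after the whole stack, floor arithmetic."""
    hw = tuple(int(x) for x in input_hw)
    if hw[0] < 1 or hw[1] < 1:
        raise GeometryError(f"input shape must be positive, got {input_hw}")
    for layer in spec.layers:
        hw = _shape_through(hw, layer)
    return hw


def count_mult_flops(spec: NetworkSpec, input_hw: Tuple[int, int],
                     n_patches: int = 1) -> CostReport:
    """Single-precision multiplication counts, exact integers.

    Each conv layer costs ``k_h*k_w*C_in*C_out*H_out*W_out`` multiplications;
    pooling layers cost zero (comparisons only). ``n_patches`` multiplies the
    whole accounting, for patch-mode networks whose per-patch cost is repeated
    over a caller-chosen number of sampled patches.
    """
    if n_patches < 1:
        raise ValidationError("n_patches must be >= 1")
    hw = tuple(int(x) for x in input_hw)
    names, mults, params = [], [], []
    for layer in spec.layers:
        hw = _shape_through(hw, layer)
        names.append(layer.name)
        if layer.kind == "conv":
            kh, kw = layer.kernel
            m = kh * kw * layer.in_channels * layer.out_channels * hw[0] * hw[1]
        else:
            m = 0
        mults.append(m * n_patches)
        params.append(layer.n_parameters)
    return CostReport(tuple(names), tuple(mults), tuple(params))


def count_parameters(spec: NetworkSpec) -> int:
    """Weight-only parameter count: sum of k_h*k_w*C_in*C_out over conv layers.

    Biases and batch-norm statistics are deliberately excluded; this is the
    convention under which the canonical stack totals 638,000 weights.
    """
    return sum(layer.n_parameters for layer in spec.layers)


def strip_padding(spec: NetworkSpec) -> NetworkSpec:
    """The same stack with every conv padding removed.

    Padding affects coverage geometry only, never capacity: the stripped stack
    has the identical parameter count and receptive-field size.
    """
    layers = tuple(
        LayerSpec(l.name, l.kind, l.kernel, l.stride, 0, l.in_channels, l.out_channels)
        for l in spec.layers
    )
    return NetworkSpec(layers, spec.input_channels, spec.name + "_nopad")


# --------------------------------------------------------------------------
# Canonical stacks. All three share kernels and channel widths (hence equal
# parameter counts); they differ only in padding and in conv6's stride.
# --------------------------------------------------------------------------

_CHANNELS = ((3, 16), (16, 32), (32, 64), (64, 64), (64, 64))


def _backbone(pad: int) -> list:
    c = _CHANNELS
    return [
        conv("conv1", 3, *c[0], pad=pad),
        maxpool("pool1"),
        conv("conv2", 3, *c[1], pad=pad),
        maxpool("pool2"),
        conv("conv3", 3, *c[2], pad=pad),
        conv("conv4", 3, *c[3], pad=pad),
        conv("conv5", 3, *c[4], pad=pad),
        maxpool("pool3"),
    ]


def _head(conv6_stride: int) -> list:
    return [
        conv("conv6", 8, 64, 128, stride=conv6_stride),
        conv("conv7", 1, 128, 128),
        conv("conv8", 1, 128, 1),
    ]


def tasselnetv2_spec() -> NetworkSpec:
    """Fully convolutional variant: pad 1 on conv1-conv5, conv6 stride 2.

    Geometry: receptive field 94, total stride 2^4 = 16, accumulated
    padding 15; weight-only parameters 638,000.
    """
    return NetworkSpec(tuple(_backbone(1) + _head(2)), 3, "tasselnetv2")


def tasselnet_spec() -> NetworkSpec:
    """Patch-mode baseline: padded convs, 64x64 input -> one local count."""
    return NetworkSpec(tuple(_backbone(1) + _head(1)), 3, "tasselnet")


def tasselnet_ctx_spec() -> NetworkSpec:
    """Patch-mode with context: all padding removed, 94x94 input -> one count."""
    return NetworkSpec(tuple(_backbone(0) + _head(1)), 3, "tasselnet_ctx")


# --------------------------------------------------------------------------
# Serialization (plain hierarchical YAML, one document per network)
# --------------------------------------------------------------------------

def spec_to_dict(spec: NetworkSpec) -> dict:
    return {
        "name": spec.name,
        "input_channels": spec.input_channels,
        "layers": [
            {k: v for k, v in asdict(l).items() if v is not None}
            for l in spec.layers
        ],
    }


def spec_from_dict(d: dict) -> NetworkSpec:
    try:
        layers = tuple(
            LayerSpec(
                name=l["name"],
                kind=l["kind"],
                kernel=tuple(l["kernel"]),
                stride=l.get("stride", 1),
                padding=l.get("padding", 0),
                in_channels=l.get("in_channels"),
                out_channels=l.get("out_channels"),
            )
            for l in d["layers"]
        )
    except KeyError as e:
        raise ValidationError(f"network config missing field: {e}") from e
    return NetworkSpec(layers, d.get("input_channels", 3), d.get("name", "network"))


def dump_spec(spec: NetworkSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> NetworkSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
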