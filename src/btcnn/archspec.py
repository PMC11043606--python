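"""Backend-independent description of the balanced binary-tree CNN.

The architecture is a binary tree of convolution groups: a *broadening*
part in which each level doubles the number of groups (1, 2, 4, 8 ... ),
a *shrinking* part in which sibling leaf outputs are added pairwise and
re-converged through small convolution groups whose outputs are
concatenated, and a dense classifier head ending in a softmax layer.

Two group flavours exist:

* convolution group -- 3x3 convolution (bias, ReLU) -> batch norm ->
  2x2/2 average pool;
* depthwise-separable group -- 3x3 depthwise convolution (bias, ReLU) ->
  batch norm -> 1x1 pointwise convolution (bias, ReLU) -> batch norm ->
  2x2/2 average pool.

This module carries no numerics: it provides the spec types plus
*analytic* parameter-count and output-shape calculators that serve as the
independent oracle for the executable network built in
:mod:`btcnn.netcore`.  Counting convention: every convolution (spatial,
depthwise or pointwise) carries a bias, and every batch normalisation
contributes 2 trainable (gamma, beta) and 2 non-trainable (moving mean,
moving variance) parameters per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Union

import pandas as pd
import yaml

__all__ = [
    "InvalidSpecError",
    "GroupKind",
    "PoolDescriptor",
    "GroupSpec",
    "DenseSpec",
    "MergeSpec",
    "BTCNNSpec",
    "ParamCount",
    "Component",
    "ShapeTrace",
    "conv_group_param_count",
    "ds_group_param_count",
    "dense_param_count",
    "group_param_count",
    "enumerate_components",
    "propagate_shapes",
    "count_model_params",
    "count_classifier_params",
    "count_merge_params",
    "count_broadening_params",
    "default_btcnn_spec",
    "validate_spec",
    "spec_to_yaml",
    "spec_from_yaml",
    "parameter_report",
    "write_parameter_report",
]


class InvalidSpecError(ValueError):
    """Raised when an architecture description violates its invariants."""


class GroupKind(Enum):
    CONV = "conv"
    DEPTHWISE_SEPARABLE = "depthwise_separable"


@dataclass(frozen=True)
class PoolDescriptor:
    """2-D pooling descriptor; the published groups all use AVG 2x2/2."""

    window: tuple[int, int] = (2, 2)
    stride: tuple[int, int] = (2, 2)
    mode: str = "avg"


@dataclass(frozen=True)
class GroupSpec:
    """One tree node: a convolution or depthwise-separable group.

    ``kernels`` is the number of output channels (the X of the published
    block diagram).  Spatial kernels are 3x3, stride 1, 'same' padding;
    the pointwise kernel (depthwise-separable only) is 1x1.
    """

    kind: GroupKind
    kernels: int
    spatial_kernel: tuple[int, int] = (3, 3)
    pointwise_kernel: tuple[int, int] = (1, 1)
    stride: tuple[int, int] = (1, 1)
    padding: str = "same"
    pool: PoolDescriptor = field(default_factory=PoolDescriptor)


@dataclass(frozen=True)
class DenseSpec:
    """A fully connected layer; dropout (if any) follows the activation."""

    width: int
    dropout_rate: float = 0.0
    activation: str = "relu"  # "relu" or "softmax"


@dataclass(frozen=True)
class MergeSpec:
    """Shrinking part: pairwise adds followed by one group per merged tensor,
    then channel concatenation."""

    group: GroupSpec


@dataclass(frozen=True)
class BTCNNSpec:
    """Full architecture: input shape, broadening levels, merge plan, head."""

    input_shape: tuple[int, int, int]
    levels: tuple[tuple[GroupSpec, ...], ...]
    merge: MergeSpec
    classifier: tuple[DenseSpec, ...]

    @property
    def n_classes(self) -> int:
        return self.classifier[-1].width


@dataclass(frozen=True)
class ParamCount:
    """Trainable / non-trainable / total parameter tallies."""

    trainable: int
    non_trainable: int
    per_component: dict | None = field(default=None, compare=False)

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable

    def __add__(self, other: "ParamCount") -> "ParamCount":
        return ParamCount(
            self.trainable + other.trainable,
            self.non_trainable + other.non_trainable,
        )

    @classmethod
    def zero(cls) -> "ParamCount":
        return cls(0, 0)


ShapeLike = Union[tuple[int, int, int], int]


@dataclass(frozen=True)
class Component:
    """One node of the unrolled architecture graph.

    ``role`` is one of input/group/add/concat/flatten/dense; ``inputs``
    names the upstream components; ``fan_in`` is the input channel count
    for groups and the input width for dense layers.
    """

    label: str
    role: str
    inputs: tuple[str, ...]
    output_shape: ShapeLike
    params: ParamCount
    spec: GroupSpec | DenseSpec | None = None
    fan_in: int | None = None


@dataclass(frozen=True)
class ShapeTrace:
    """Ordered (component label, output shape) pairs for a spec."""

    entries: tuple[tuple[str, ShapeLike], ...]

    def __iter__(self):
        return iter(self.entries)

    def shape_of(self, label: str) -> ShapeLike:
        for name, shape in self.entries:
            if name == label:
                return shape
        raise KeyError(label)

    @property
    def flat_length(self) -> int:
        for name, shape in self.entries:
            if name == "Flatten":
                return shape
        raise KeyError("Flatten")

    @property
    def shapes(self) -> tuple[ShapeLike, ...]:
        return tuple(shape for _, shape in self.entries)


# ---------------------------------------------------------------------------
# analytic parameter counting


def _require_positive(**kwargs: int) -> None:
    for name, value in kwargs.items():
        if not isinstance(value, (int,)) or isinstance(value, bool) or value < 1:
            raise InvalidSpecError(f"{name} must be a positive integer, got {value!r}")


def conv_group_param_count(in_channels: int, kernels: int) -> ParamCount:
    """Parameters of a convolution group (3x3 conv + bias, batch norm).

    Trainable: ``9*c_in*k`` conv weights, ``k`` biases, ``2k`` batch-norm
    scale/shift.  Non-trainable: ``2k`` batch-norm moving statistics.
    """
    _require_positive(in_channels=in_channels, kernels=kernels)
    trainable = 9 * in_channels * kernels + kernels + 2 * kernels
    return ParamCount(trainable=trainable, non_trainable=2 * kernels)


def ds_group_param_count(in_channels: int, kernels: int) -> ParamCount:
    """Parameters of a depthwise-separable group.

    Depthwise 3x3 stage: ``9*c_in`` weights + ``c_in`` biases + batch norm
    on ``c_in`` channels.  Pointwise 1x1 stage: ``c_in*k`` weights + ``k``
    biases + batch norm on ``k`` channels.
    """
    _require_positive(in_channels=in_channels, kernels=kernels)
    dw_trainable = 9 * in_channels + in_channels + 2 * in_channels
    pw_trainable = in_channels * kernels + kernels + 2 * kernels
    return ParamCount(
        trainable=dw_trainable + pw_trainable,
        non_trainable=2 * in_channels + 2 * kernels,
    )


def dense_param_count(in_width: int, out_width: int) -> ParamCount:
    """Fully connected layer: weights + bias, all trainable."""
    _require_positive(in_width=in_width, out_width=out_width)
    return ParamCount(trainable=in_width * out_width + out_width, non_trainable=0)


def group_param_count(group: GroupSpec, in_channels: int) -> ParamCount:
    if group.kind is GroupKind.CONV:
        return conv_group_param_count(in_channels, group.kernels)
    return ds_group_param_count(in_channels, group.kernels)


# ---------------------------------------------------------------------------
# graph enumeration


class _Labeller:
    """Keras-style running labels: first occurrence unnumbered, then ' 1'..."""

    def __init__(self) -> None:
        self._counts: dict[str, int] = {}

    def next(self, base: str) -> str:
        n = self._counts.get(base, 0)
        self._counts[base] = n + 1
        return base if n == 0 else f"{base} {n}"


def _pooled(size: int, window: int, stride: int) -> int:
    out = (size - window) // stride + 1
    if out < 1:
        raise InvalidSpecError(
            f"spatial dimension collapses to {out} through a {window}x{window} pool"
        )
    return out


def _group_output_shape(shape: tuple[int, int, int], group: GroupSpec) -> tuple[int, int, int]:
    h, w, _ = shape
    if group.padding != "same":
        raise InvalidSpecError("only 'same' spatial padding is supported")
    pw, ph = group.pool.window
    sw, sh = group.pool.stride
    return (_pooled(h, pw, sw), _pooled(w, ph, sh), group.kernels)


def enumerate_components(spec: BTCNNSpec) -> list[Component]:
    """Unroll a spec into its labelled component graph, in topological order.

    Labels follow the published report naming ("Convolution group 1",
    "Depthwise convolution group 4", "Dense 3 + Dropout 1", ...) so
    parameter reports are directly comparable with the published table.
    """
    if not spec.levels or not spec.levels[0]:
        raise InvalidSpecError("spec has no broadening levels")
    if not spec.classifier:
        raise InvalidSpecError("spec has no classifier head")

    labels = _Labeller()
    dense_labels = _Labeller()
    dropout_labels = _Labeller()
    components: list[Component] = [
        Component("Input", "input", (), spec.input_shape, ParamCount.zero())
    ]

    base = {
        GroupKind.CONV: "Convolution group",
        GroupKind.DEPTHWISE_SEPARABLE: "Depthwise convolution group",
    }

    def add_group(group: GroupSpec, parent: Component) -> Component:
        shape = parent.output_shape
        comp = Component(
            label=labels.next(base[group.kind]),
            role="group",
            inputs=(parent.label,),
            output_shape=_group_output_shape(shape, group),
            params=group_param_count(group, shape[2]),
            spec=group,
            fan_in=shape[2],
        )
        components.append(comp)
        return comp

    # broadening part: group i of level l feeds groups 2i, 2i+1 of level l+1
    current = [components[0]]
    for li, level in enumerate(spec.levels):
        if li == 0:
            if len(level) != 1:
                raise InvalidSpecError("the first broadening level must have one group")
        elif len(level) != 2 * len(current):
            raise InvalidSpecError(
                f"level of size {len(level)} does not double the previous "
                f"level of size {len(current)}"
            )
        parents = current
        current = []
        for i, group in enumerate(level):
            parent = parents[i // 2] if len(level) > len(parents) else parents[i]
            current.append(add_group(group, parent))

    # shrinking part: pairwise adds, one merge group each, concatenation
    leaves = current
    if len(leaves) % 2 != 0:
        raise InvalidSpecError("merge requires an even number of leaf groups")
    merged: list[Component] = []
    for j in range(len(leaves) // 2):
        a, b = leaves[2 * j], leaves[2 * j + 1]
        if a.output_shape != b.output_shape:
            raise InvalidSpecError(
                f"cannot add tensors of shapes {a.output_shape} and {b.output_shape}"
            )
        add_comp = Component(
            label=labels.next("Add"),
            role="add",
            inputs=(a.label, b.label),
            output_shape=a.output_shape,
            params=ParamCount.zero(),
        )
        components.append(add_comp)
        merged.append(add_group(spec.merge.group, add_comp))

    concat_shape = (
        merged[0].output_shape[0],
        merged[0].output_shape[1],
        sum(c.output_shape[2] for c in merged),
    )
    concat = Component(
        labels.next("Concatenate"),
        "concat",
        tuple(c.label for c in merged),
        concat_shape,
        ParamCount.zero(),
    )
    components.append(concat)

    flat = Component(
        labels.next("Flatten"),
        "flatten",
        (concat.label,),
        int(math.prod(concat_shape)),
        ParamCount.zero(),
    )
    components.append(flat)

    # classifier head
    prev = flat
    width = flat.output_shape
    for i, dense in enumerate(spec.classifier):
        if dense.activation == "softmax" and i != len(spec.classifier) - 1:
            raise InvalidSpecError("softmax is only allowed on the final dense layer")
        if not 0.0 <= dense.dropout_rate < 1.0:
            raise InvalidSpecError(f"dropout rate {dense.dropout_rate} outside [0, 1)")
        label = dense_labels.next("Dense")
        if dense.dropout_rate > 0:
            label = f"{label} + {dropout_labels.next('Dropout')}"
        comp = Component(
            label=label,
            role="dense",
            inputs=(prev.label,),
            output_shape=dense.width,
            params=dense_param_count(width, dense.width),
            spec=dense,
            fan_in=width,
        )
        components.append(comp)
        prev, width = comp, dense.width
    if spec.classifier[-1].activation != "softmax":
        raise InvalidSpecError("final classifier layer must be softmax")
    return components


def propagate_shapes(spec: BTCNNSpec) -> ShapeTrace:
    """Trace output shapes through every component of the unrolled graph.

    Pooling of odd spatial sizes floors (no padding), so a 25-pixel map
    pools to 12; a shape reaching zero raises :class:`InvalidSpecError`.
    """
    return ShapeTrace(
        tuple((c.label, c.output_shape) for c in enumerate_components(spec))
    )


def count_model_params(spec: BTCNNSpec) -> ParamCount:
    """Aggregate analytic parameter count, with a per-component breakdown."""
    components = enumerate_components(spec)
    per_component = {
        c.label: c.params for c in components if c.params.total > 0
    }
    agg = ParamCount.zero()
    for p in per_component.values():
        agg = agg + p
    return ParamCount(agg.trainable, agg.non_trainable, per_component=per_component)


def count_classifier_params(spec: BTCNNSpec) -> ParamCount:
    """Parameters of the dense head alone (dropout contributes nothing)."""
    agg = ParamCount.zero()
    for c in enumerate_components(spec):
        if c.role == "dense":
            agg = agg + c.params
    return agg


def count_merge_params(spec: BTCNNSpec) -> ParamCount:
    """Parameters of the shrinking part: the post-add merge groups."""
    components = enumerate_components(spec)
    add_labels = {c.label for c in components if c.role == "add"}
    agg = ParamCount.zero()
    for c in components:
        if c.role == "group" and c.inputs[0] in add_labels:
            agg = agg + c.params
    return agg


def count_broadening_params(spec: BTCNNSpec) -> ParamCount:
    """Parameters of the broadening tree (everything before the adds)."""
    components = enumerate_components(spec)
    add_labels = {c.label for c in components if c.role == "add"}
    agg = ParamCount.zero()
    for c in components:
        if c.role == "group" and c.inputs[0] not in add_labels:
            agg = agg + c.params
    return agg


# ---------------------------------------------------------------------------
# the published architecture


def default_btcnn_spec() -> BTCNNSpec:
    """The published 4-class architecture for 200x200 grayscale input.

    Broadening levels of 1/2/4/8 groups with 256/128/64/32 kernels (the
    first two levels convolution groups, the last two depthwise
    separable), pairwise add-merges into four 16-kernel convolution
    groups, and a dense head 250-250-250-100-100-100-60-30-15-4 with
    dropout 0.2 after the first 250 layer and 0.1 / 0.05 after the first
    two 100 layers.
    """
    conv = lambda k: GroupSpec(GroupKind.CONV, k)  # noqa: E731
    ds = lambda k: GroupSpec(GroupKind.DEPTHWISE_SEPARABLE, k)  # noqa: E731
    levels = (
        (conv(256),),
        tuple(conv(128) for _ in range(2)),
        tuple(ds(64) for _ in range(4)),
        tuple(ds(32) for _ in range(8)),
    )
    classifier = (
        DenseSpec(250, dropout_rate=0.2),
        DenseSpec(250),
        DenseSpec(250),
        DenseSpec(100, dropout_rate=0.1),
        DenseSpec(100, dropout_rate=0.05),
        DenseSpec(100),
        DenseSpec(60),
        DenseSpec(30),
        DenseSpec(15),
        DenseSpec(4, activation="softmax"),
    )
    return BTCNNSpec(
        input_shape=(200, 200, 1),
        levels=levels,
        merge=MergeSpec(group=conv(16)),
        classifier=classifier,
    )


def validate_spec(spec: BTCNNSpec) -> list[str]:
    """Check all structural invariants; returns violations as data."""
    violations: list[str] = []
    if len(spec.input_shape) != 3 or any(d < 1 for d in spec.input_shape):
        violations.append(f"invalid input shape {spec.input_shape}")
    for li, level in enumerate(spec.levels):
        for gi, g in enumerate(level):
            if g.kernels < 1:
                violations.append(f"level {li} group {gi}: kernels must be >= 1")
            if any(s < 1 for s in g.stride):
                violations.append(f"level {li} group {gi}: stride must be >= 1")
            if any(w < 1 for w in g.pool.window) or any(s < 1 for s in g.pool.stride):
                violations.append(f"level {li} group {gi}: pool window/stride must be >= 1")
    if spec.merge.group.kernels < 1:
        violations.append("merge group: kernels must be >= 1")
    for di, d in enumerate(spec.classifier):
        if d.width < 1:
            violations.append(f"classifier layer {di}: width must be >= 1")
        if not 0.0 <= d.dropout_rate < 1.0:
            violations.append(f"classifier layer {di}: dropout rate outside [0, 1)")
        if d.activation == "softmax" and di != len(spec.classifier) - 1:
            violations.append(f"classifier layer {di}: softmax before the final layer")
    if spec.classifier and spec.classifier[-1].activation != "softmax":
        violations.append("final classifier layer must be softmax")
    if not violations:
        try:
            enumerate_components(spec)
        except InvalidSpecError as exc:
            violations.append(str(exc))
    return violations


# ---------------------------------------------------------------------------
# serialization and reporting


def _group_to_dict(g: GroupSpec) -> dict:
    return {
        "kind": g.kind.value,
        "kernels": g.kernels,
        "spatial_kernel": list(g.spatial_kernel),
        "pointwise_kernel": list(g.pointwise_kernel),
        "stride": list(g.stride),
        "padding": g.padding,
        "pool": {
            "window": list(g.pool.window),
            "stride": list(g.pool.stride),
            "mode": g.pool.mode,
        },
    }


def _group_from_dict(d: dict) -> GroupSpec:
    return GroupSpec(
        kind=GroupKind(d["kind"]),
        kernels=int(d["kernels"]),
        spatial_kernel=tuple(d.get("spatial_kernel", (3, 3))),
        pointwise_kernel=tuple(d.get("pointwise_kernel", (1, 1))),
        stride=tuple(d.get("stride", (1, 1))),
        padding=d.get("padding", "same"),
        pool=PoolDescriptor(
            window=tuple(d["pool"]["window"]),
            stride=tuple(d["pool"]["stride"]),
            mode=d["pool"]["mode"],
        )
        if "pool" in d
        else PoolDescriptor(),
    )


def spec_to_yaml(spec: BTCNNSpec) -> str:
    doc = {
        "input_shape": list(spec.input_shape),
        "levels": [[_group_to_dict(g) for g in level] for level in spec.levels],
        "merge": {"group": _group_to_dict(spec.merge.group)},
        "classifier": [
            {"width": d.width, "dropout_rate": d.dropout_rate, "activation": d.activation}
            for d in spec.classifier
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> BTCNNSpec:
    doc = yaml.safe_load(text)
    return BTCNNSpec(
        input_shape=tuple(doc["input_shape"]),
        levels=tuple(
            tuple(_group_from_dict(g) for g in level) for level in doc["levels"]
        ),
        merge=MergeSpec(group=_group_from_dict(doc["merge"]["group"])),
        classifier=tuple(
            DenseSpec(
                width=int(d["width"]),
                dropout_rate=float(d.get("dropout_rate", 0.0)),
                activation=d.get("activation", "relu"),
            )
            for d in doc["classifier"]
        ),
    )


def _shape_str(shape: ShapeLike) -> str:
    if isinstance(shape, int):
        return str(shape)
    return "*".join(str(d) for d in shape)


def parameter_report(spec: BTCNNSpec) -> pd.DataFrame:
    """Component-level parameter report, diffable against the published table."""
    rows = []
    for c in enumerate_components(spec):
        rows.append(
            {
                "component": c.label,
                "connected_to": "; ".join(c.inputs),
                "output_shape": _shape_str(c.output_shape),
                "trainable": c.params.trainable,
                "non_trainable": c.params.non_trainable,
                "total": c.params.total,
            }
        )
    return pd.DataFrame(rows)


def write_parameter_report(spec: BTCNNSpec, path) -> None:
    parameter_report(spec).to_csv(path, index=False)
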