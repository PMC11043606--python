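"""Executable balanced-tree network built from a :class:`BTCNNSpec`.

``build_network`` unrolls the same component graph as the analytic
calculators in :mod:`btcnn.archspec`, so the built network's parameter
tally can be checked against the analytic oracle component by component.
Training is plain mini-batch Adam on the categorical cross-entropy, with
one integer seed driving weight initialisation, shuffling and dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..archspec import (
    BTCNNSpec,
    Component,
    GroupKind,
    InvalidSpecError,
    ParamCount,
    enumerate_components,
    validate_spec,
)
from . import layers as L
from .reference import softmax

__all__ = ["TrainConfig", "TrainingHistory", "TreeNetwork", "build_network", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Published protocol: Adam at lr 1e-4, 20 epochs, batch size 24."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    epochs: int = 20
    batch_size: int = 24
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise InvalidSpecError("learning rate must be >= 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise InvalidSpecError("epochs must be >= 0 and batch size >= 1")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.loss) + 1),
                "loss": self.loss,
                "accuracy": self.accuracy,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Node:
    def __init__(self, component: Component, stack: list[L.Layer]) -> None:
        self.component = component
        self.label = component.label
        self.role = component.role
        self.inputs = component.inputs
        self.stack = stack

    def forward(self, xs: list[np.ndarray], training: bool) -> np.ndarray:
        if self.role == "add":
            out = xs[0] + xs[1]
        elif self.role == "concat":
            self._split = np.cumsum([x.shape[-1] for x in xs])[:-1]
            out = np.concatenate(xs, axis=-1)
        else:
            out = xs[0]
        for layer in self.stack:
            out = layer.forward(out, training)
        return out

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        for layer in reversed(self.stack):
            dout = layer.backward(dout)
        if self.role == "add":
            return [dout, dout]
        if self.role == "concat":
            return np.split(dout, self._split, axis=-1)
        return [dout]


def _group_stack(component: Component, rng: np.random.Generator) -> list[L.Layer]:
    g = component.spec
    c_in = component.fan_in
    stack: list[L.Layer] = []
    if g.kind is GroupKind.CONV:
        stack += [
            L.Conv2DSame(c_in, g.kernels, g.spatial_kernel, rng),
            L.ReLU(),
            L.BatchNorm(g.kernels),
        ]
    else:
        stack += [
            L.DepthwiseConv2DSame(c_in, g.spatial_kernel, rng),
            L.ReLU(),
            L.BatchNorm(c_in),
            L.PointwiseConv(c_in, g.kernels, rng),
            L.ReLU(),
            L.BatchNorm(g.kernels),
        ]
    stack.append(L.AvgPool(g.pool.window))
    return stack


class TreeNetwork:
    """Forward/backward executable graph mirroring the spec's components."""

    def __init__(self, spec: BTCNNSpec, seed: int = 0) -> None:
        problems = validate_spec(spec)
        if problems:
            raise InvalidSpecError("; ".join(problems))
        self.spec = spec
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.nodes: list[_Node] = []
        for comp in enumerate_components(spec):
            if comp.role == "input":
                continue
            if comp.role == "group":
                stack = _group_stack(comp, self.rng)
            elif comp.role == "dense":
                d = comp.spec
                stack = [L.Dense(comp.fan_in, d.width, self.rng)]
                if d.activation == "relu":
                    stack.append(L.ReLU())
                if d.dropout_rate > 0:
                    stack.append(L.Dropout(d.dropout_rate, self.rng))
            elif comp.role == "flatten":
                stack = [L.Flatten()]
            else:  # add / concat
                stack = []
            self.nodes.append(_Node(comp, stack))
        self._final = self.nodes[-1].label

    # -- execution ---------------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Pre-softmax activations of the final dense layer."""
        x = np.asarray(x, dtype=L.DTYPE)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec "
                f"{tuple(self.spec.input_shape)}"
            )
        outputs = {"Input": x}
        for node in self.nodes:
            xs = [outputs[name] for name in node.inputs]
            outputs[node.label] = node.forward(xs, training)
        self._outputs = outputs
        return outputs[self._final]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities, one row per input image."""
        return softmax(self.forward_logits(x, training))

    def backward(self, dlogits: np.ndarray) -> None:
        grads: dict[str, np.ndarray] = {self._final: dlogits}
        for node in reversed(self.nodes):
            dins = node.backward(grads.pop(node.label))
            for name, d in zip(node.inputs, dins):
                if name in grads:
                    grads[name] = grads[name] + d
                else:
                    grads[name] = d

    # -- introspection -----------------------------------------------------

    def trainable_layers(self) -> list[L.Layer]:
        return [layer for node in self.nodes for layer in node.stack if layer.params]

    def count_params(self) -> ParamCount:
        """Tally of the actually-allocated arrays, per component and overall."""
        per_component: dict[str, ParamCount] = {}
        agg = ParamCount.zero()
        for node in self.nodes:
            t = nt = 0
            for layer in node.stack:
                lt, lnt = layer.param_count()
                t, nt = t + lt, nt + lnt
            if t + nt:
                pc = ParamCount(t, nt)
                per_component[node.label] = pc
                agg = agg + pc
        return ParamCount(agg.trainable, agg.non_trainable, per_component=per_component)

    # -- checkpointing -----------------------------------------------------

    def save_weights(self, path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for ni, node in enumerate(self.nodes):
            for li, layer in enumerate(node.stack):
                for key, value in layer.params.items():
                    arrays[f"{ni}.{li}.{key}"] = value
                if isinstance(layer, L.BatchNorm):
                    arrays[f"{ni}.{li}.moving_mean"] = layer.moving_mean
                    arrays[f"{ni}.{li}.moving_var"] = layer.moving_var
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for ni, node in enumerate(self.nodes):
                for li, layer in enumerate(node.stack):
                    for key in layer.params:
                        layer.params[key] = data[f"{ni}.{li}.{key}"]
                    if isinstance(layer, L.BatchNorm):
                        layer.moving_mean = data[f"{ni}.{li}.moving_mean"]
                        layer.moving_var = data[f"{ni}.{li}.moving_var"]


def build_network(spec: BTCNNSpec, seed: int = 0) -> TreeNetwork:
    """Build an executable network; refuses specs with validation errors."""
    return TreeNetwork(spec, seed=seed)


class _Adam:
    def __init__(self, net: TreeNetwork, config: TrainConfig) -> None:
        self.cfg = config
        self.layers = net.trainable_layers()
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for layer in self.layers
        ]
        self.t = 0

    def step(self) -> None:
        cfg = self.cfg
        self.t += 1
        lr_t = cfg.learning_rate * (
            np.sqrt(1 - cfg.beta2**self.t) / (1 - cfg.beta1**self.t)
        )
        for layer, m, v in zip(self.layers, self.m, self.v):
            for key, g in layer.grads.items():
                g = g.astype(np.float32)
                m[key] = cfg.beta1 * m[key] + (1 - cfg.beta1) * g
                v[key] = cfg.beta2 * v[key] + (1 - cfg.beta2) * g * g
                layer.params[key] -= lr_t * m[key] / (np.sqrt(v[key]) + cfg.epsilon)


def train(
    network: TreeNetwork,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
) -> TrainingHistory:
    """Mini-batch training on one-hot labels; returns per-epoch loss/accuracy.

    Loss and accuracy are accumulated over the training batches of each
    epoch (predictions taken before the weight update for that batch).
    """
    config = config or TrainConfig()
    x = np.asarray(images, dtype=L.DTYPE)
    if x.ndim == 3:
        x = x[..., None]
    y = np.asarray(labels, dtype=L.DTYPE)
    if x.shape[1:] != tuple(network.spec.input_shape):
        raise ValueError(
            f"image shape {x.shape[1:]} does not match spec "
            f"{tuple(network.spec.input_shape)}"
        )
    if y.ndim != 2 or y.shape[0] != x.shape[0] or y.shape[1] != network.spec.n_classes:
        raise ValueError("labels must be one-hot with one row per image")

    rng = np.random.default_rng(config.seed)
    opt = _Adam(network, config)
    history = TrainingHistory()
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        total_loss = 0.0
        total_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = network.forward_logits(xb, training=True)
            probs = softmax(logits)
            clipped = np.clip(probs, 1e-12, 1.0)
            total_loss += float(-(yb * np.log(clipped)).sum())
            total_correct += int(
                (probs.argmax(axis=1) == yb.argmax(axis=1)).sum()
            )
            network.backward((probs - yb) / len(idx))
            opt.step()
        history.loss.append(total_loss / n)
        history.accuracy.append(total_correct / n)
    return history
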