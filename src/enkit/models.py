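"""Baseline EEG CNN classifiers with an optional EnK insertion point.

Four compact architectures are provided, following their published
configurations (EEGNet-8,2; ShallowConvNet; DeepConvNet; a recurrent
CNN with five recurrent-convolution layers):

* ``eegnet`` — temporal convolution, depthwise spatial filter,
  separable convolution, two average-pooling stages;
* ``shallowconvnet`` — temporal + spatial convolution, squaring
  nonlinearity, overlapping average pool, log activation;
* ``deepconvnet`` — four convolutional blocks with max pooling;
* ``rcnn`` — an input convolution, a spatial filter and five
  recurrent-convolution blocks with shared intra-block weights.

When ``enk_enabled`` the time-encoding EnK layer is spliced in directly
after the first convolution; it is shape-preserving, so every
downstream layer is untouched and the parameter count grows by exactly
``2*k' + l*m`` where ``k'`` is the time length after the first
convolution.  A ``scale`` multiplier shrinks filter counts for
desk-scale experiments without changing the topology.

Input layout is ``(batch, 1, channels, samples)``; 3-axis epoch arrays
are reshaped at the model boundary.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .errors import ConfigurationError, DimensionError

ARCHITECTURES = ("eegnet", "shallowconvnet", "deepconvnet", "rcnn")
CHECKPOINT_VERSION = 1


@dataclass
class EnKConfig:
    """Dimensions of the EnK artifact kernel and affine sharing flag."""

    l: int = 1
    m: int = 7
    shared_affine: bool = True


@dataclass
class ModelSpec:
    """Declarative description of one classifier; fully determines the
    parameter count (given the init seed, the weights too)."""

    architecture: str
    n_channels: int
    n_samples: int
    n_classes: int = 2
    enk_enabled: bool = False
    enk_config: EnKConfig = field(default_factory=EnKConfig)
    dropout_rate: float = 0.25
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if not (0.15 <= self.dropout_rate <= 0.75):
            raise ConfigurationError(
                f"dropout_rate {self.dropout_rate} outside [0.15, 0.75]")
        if self.n_channels < 1 or self.n_samples < 1:
            raise ConfigurationError("n_channels and n_samples must be >= 1")
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")
        if isinstance(self.enk_config, dict):
            self.enk_config = EnKConfig(**self.enk_config)


@dataclass
class SummaryRow:
    name: str
    output_shape: tuple[int, ...]
    n_params: int


@dataclass
class ModelSummary:
    rows: list[SummaryRow]
    total_params: int

    def as_text(self) -> str:
        lines = [f"{'layer':<18}{'output shape':<22}{'params':>10}"]
        for r in self.rows:
            lines.append(f"{r.name:<18}{str(r.output_shape):<22}{r.n_params:>10}")
        lines.append(f"{'total':<40}{self.total_params:>10}")
        return "\n".join(lines)


class Model:
    """A built classifier: a layer stack plus the spec that produced it.

    ``forward``/``predict_proba`` return class probabilities (softmax
    head, rows sum to one); ``logits`` exposes the pre-softmax scores
    used for training and Grad-CAM.
    """

    def __init__(self, spec: ModelSpec, net: nn.Network):
        self.spec = spec
        self.net = net

    # -- inference ---------------------------------------------------------
    def _as_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:  # (epochs, channels, samples) -> add the map axis
            x = x[:, None, :, :]
        if x.ndim != 4:
            raise DimensionError(f"expected 3- or 4-axis input, got {x.ndim}")
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._as_input(x))

    predict_proba = forward

    def logits(self, x: np.ndarray, training: bool = False,
               rng: Optional[np.random.Generator] = None) -> np.ndarray:
        return self.net.forward(self._as_input(x), training=training, rng=rng)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=1)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        spec = asdict(self.spec)
        spec["checkpoint_version"] = CHECKPOINT_VERSION
        (path / "spec.json").write_text(json.dumps(spec, indent=2))
        np.savez(path / "weights.npz", **self.net.get_state())

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        path = Path(path)
        raw = json.loads((path / "spec.json").read_text())
        version = raw.pop("checkpoint_version", None)
        if version != CHECKPOINT_VERSION:
            raise ConfigurationError(
                f"checkpoint version {version} unsupported "
                f"(expected {CHECKPOINT_VERSION})")
        spec = ModelSpec(**raw)
        model = build_model(spec, init_seed=0)
        with np.load(path / "weights.npz") as npz:
            model.net.set_state({k: npz[k] for k in npz.files})
        return model


# ---------------------------------------------------------------------------
# architecture builders
# ---------------------------------------------------------------------------


def _scaled(base: int, scale: float) -> int:
    return max(1, round(base * scale))


def _maybe_enk(layers: list[nn.Layer], spec: ModelSpec,
               n_after: int, k_after: int) -> None:
    if spec.enk_enabled:
        cfg = spec.enk_config
        layers.append(nn.EnKLayer(n=n_after, k=k_after, l=cfg.l, m=cfg.m,
                                  shared_affine=cfg.shared_affine, name="enk"))


def _dense_from(layers: list[nn.Layer], input_shape, n_classes: int) -> None:
    shape: tuple[int, ...] = (1, *input_shape)
    for layer in layers:
        shape = layer.output_shape(shape)
    layers.append(nn.Flatten())
    layers.append(nn.Dense(int(np.prod(shape[1:])), n_classes, name="classifier"))


def _build_eegnet(spec: ModelSpec) -> list[nn.Layer]:
    C, T = spec.n_channels, spec.n_samples
    F1 = _scaled(8, spec.scale)
    D = 2
    F2 = F1 * D
    klen = min(64, T)
    p = spec.dropout_rate
    layers: list[nn.Layer] = [
        nn.Conv2d(1, F1, (1, klen), padding="same", bias=False, name="conv1"),
    ]
    _maybe_enk(layers, spec, n_after=C, k_after=T)
    layers += [
        nn.BatchNorm2d(F1, name="bn1"),
        nn.DepthwiseConv2d(F1, D, (C, 1), name="depthwise"),
        nn.BatchNorm2d(F1 * D, name="bn2"),
        nn.Activation("elu", name="elu1"),
        nn.AvgPool2d((1, 4), name="pool1"),
        nn.Dropout(p, name="drop1"),
        nn.DepthwiseConv2d(F1 * D, 1, (1, max(1, min(16, T // 4))), padding="same",
                           name="sep_depth"),
        nn.Conv2d(F1 * D, F2, (1, 1), name="sep_point"),
        nn.BatchNorm2d(F2, name="bn3"),
        nn.Activation("elu", name="elu2"),
        nn.AvgPool2d((1, 8), name="pool2"),
        nn.Dropout(p, name="drop2"),
    ]
    _dense_from(layers, (1, C, T), spec.n_classes)
    return layers


def _build_shallow(spec: ModelSpec) -> list[nn.Layer]:
    C, T = spec.n_channels, spec.n_samples
    F = _scaled(40, spec.scale)
    layers: list[nn.Layer] = [
        nn.Conv2d(1, F, (1, 25), name="conv1"),
    ]
    _maybe_enk(layers, spec, n_after=C, k_after=T - 24)
    layers += [
        nn.Conv2d(F, F, (C, 1), bias=False, name="conv_spatial"),
        nn.BatchNorm2d(F, name="bn1"),
        nn.Activation("square", name="square"),
        nn.AvgPool2d((1, 75), stride=(1, 15), name="pool1"),
        nn.Activation("safelog", name="log"),
        nn.Dropout(spec.dropout_rate, name="drop1"),
    ]
    _dense_from(layers, (1, C, T), spec.n_classes)
    return layers


def _build_deep(spec: ModelSpec) -> list[nn.Layer]:
    C, T = spec.n_channels, spec.n_samples
    F1 = _scaled(25, spec.scale)
    p = spec.dropout_rate
    layers: list[nn.Layer] = [
        nn.Conv2d(1, F1, (1, 10), name="conv1"),
    ]
    _maybe_enk(layers, spec, n_after=C, k_after=T - 9)
    layers += [
        nn.Conv2d(F1, F1, (C, 1), bias=False, name="conv_spatial"),
        nn.BatchNorm2d(F1, name="bn1"),
        nn.Activation("elu", name="elu1"),
        nn.MaxPool2d((1, 3), name="pool1"),
        nn.Dropout(p, name="drop1"),
    ]
    f_prev = F1
    for i, mult in enumerate((2, 4, 8), start=2):
        f = _scaled(25 * mult, spec.scale)
        layers += [
            nn.Conv2d(f_prev, f, (1, 10), bias=False, name=f"conv{i}"),
            nn.BatchNorm2d(f, name=f"bn{i}"),
            nn.Activation("elu", name=f"elu{i}"),
            nn.MaxPool2d((1, 3), name=f"pool{i}"),
            nn.Dropout(p, name=f"drop{i}"),
        ]
        f_prev = f
    _dense_from(layers, (1, C, T), spec.n_classes)
    return layers


def _build_rcnn(spec: ModelSpec) -> list[nn.Layer]:
    C, T = spec.n_channels, spec.n_samples
    F = _scaled(16, spec.scale)
    p = spec.dropout_rate
    layers: list[nn.Layer] = [
        nn.Conv2d(1, F, (1, 5), padding="same", name="conv1"),
    ]
    _maybe_enk(layers, spec, n_after=C, k_after=T)
    layers += [
        nn.BatchNorm2d(F, name="bn_in"),
        nn.Activation("elu", name="elu_in"),
        nn.Conv2d(F, F, (C, 1), bias=False, name="conv_spatial"),
        nn.BatchNorm2d(F, name="bn_spatial"),
        nn.Activation("elu", name="elu_spatial"),
    ]
    for i in range(1, 6):
        layers += [
            nn.RCL(F, F, (1, 3), iters=3, name=f"rcl{i}"),
            nn.BatchNorm2d(F, name=f"bn_rcl{i}"),
        ]
        if i < 5:
            layers.append(nn.MaxPool2d((1, 2), name=f"pool{i}"))
        layers.append(nn.Dropout(p, name=f"drop{i}"))
    layers += [
        nn.GlobalAvgPool(name="gap"),
        nn.Dense(F, spec.n_classes, name="classifier"),
    ]
    return layers


_BUILDERS = {
    "eegnet": _build_eegnet,
    "shallowconvnet": _build_shallow,
    "deepconvnet": _build_deep,
    "rcnn": _build_rcnn,
}


def _min_samples(spec: ModelSpec) -> int:
    """Smallest n_samples for which the architecture's stacked
    convolutions and poolings stay non-empty (exponential + binary search
    over the shape arithmetic only)."""

    def ok(t: int) -> bool:
        if t < 1:
            return False
        trial = ModelSpec(**{**asdict(spec), "n_samples": t,
                             "enk_config": asdict(spec.enk_config)})
        try:
            layers = _BUILDERS[spec.architecture](trial)
            shape: tuple[int, ...] = (1, 1, trial.n_channels, t)
            for layer in layers:
                shape = layer.output_shape(shape)
            return True
        except DimensionError:
            return False

    hi = 1
    while not ok(hi):
        hi *= 2
        if hi > 1 << 20:  # pragma: no cover - defensive
            raise ConfigurationError("no feasible n_samples found")
    lo = hi // 2
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


def build_model(spec: ModelSpec, init_seed: int = 0) -> Model:
    """Construct (and deterministically initialise) the requested model."""
    try:
        layers = _BUILDERS[spec.architecture](spec)
        net = nn.Network(layers, input_shape=(1, spec.n_channels, spec.n_samples))
        net.shapes()
    except DimensionError as err:
        raise ConfigurationError(
            f"{spec.architecture} needs n_samples >= {_min_samples(spec)} "
            f"for {spec.n_channels} channels (got {spec.n_samples}): {err}"
        ) from err
    net.initialize(init_seed)
    return Model(spec, net)


def summarize(model: Model) -> ModelSummary:
    """Ordered layer table (name, output shape, parameter count)."""
    rows = [
        SummaryRow(name=name, output_shape=shape, n_params=layer.n_params)
        for (name, shape), layer in zip(model.net.shapes(), model.net.layers)
    ]
    return ModelSummary(rows=rows, total_params=sum(r.n_params for r in rows))
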