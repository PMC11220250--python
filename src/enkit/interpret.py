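"""Grad-CAM interpretability for the EEG classifiers.

Class-activation maps are computed at the first convolution's output —
or at the EnK layer's output when the layer is enabled — by weighting
each feature map with the spatial mean of the class-score (logit)
gradient, summing, rectifying and max-normalising to [0, 1].  The map
lives on the target layer's (rows, time) extent; for overlay on the raw
signal it is linearly resampled along time to the input's sample count
and rendered behind the per-channel line graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .errors import ConfigurationError, DimensionError
from .models import Model

__all__ = ["GradCamMap", "gradcam", "overlay", "diff_map",
           "default_target_layer", "heat_mass_fraction"]


@dataclass
class GradCamMap:
    """Normalised class-activation map on the target layer's extent.

    ``heat`` has values in [0, 1] with max exactly 1 unless the map is
    identically zero.  ``n_samples`` is the input's sample count, the
    length to which :meth:`resampled` interpolates for overlay.
    """

    heat: np.ndarray  # (rows, time) on the target layer's extent
    target_class: int
    target_layer: str
    input_ref: str
    n_samples: int

    def resampled(self, n: int | None = None) -> np.ndarray:
        """Linear time interpolation of the heat map to ``n`` samples."""
        n = n or self.n_samples
        rows, w = self.heat.shape
        if w == n:
            return self.heat.copy()
        src = np.linspace(0.0, 1.0, w) if w > 1 else np.array([0.5])
        dst = np.linspace(0.0, 1.0, n)
        return np.stack([np.interp(dst, src, self.heat[r]) for r in range(rows)])


def default_target_layer(model: Model) -> str:
    """The EnK layer's output when enabled, else the first convolution."""
    names = [layer.name for layer in model.net.layers]
    return "enk" if "enk" in names else "conv1"


def gradcam(model: Model, epoch: np.ndarray, target_class: int,
            target_layer: str | None = None, input_ref: str = "") -> GradCamMap:
    """Gradient-weighted class-activation map for one input epoch.

    Feature-map weights are the spatial mean of d(logit of
    ``target_class``)/d(activation); the heat map is the rectified
    weighted sum, max-normalised (an all-zero map stays zero).
    """
    if target_layer is None:
        target_layer = default_target_layer(model)
    if not (0 <= target_class < model.spec.n_classes):
        raise ConfigurationError(
            f"target_class {target_class} out of range for "
            f"{model.spec.n_classes} classes")
    idx = model.net.find(target_layer)  # KeyError on unknown layer

    x = np.asarray(epoch, dtype=float)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[0] != 1:
        raise DimensionError("gradcam expects a single epoch (channels, samples)")

    act = None
    h = x
    for i, layer in enumerate(model.net.layers):
        h = layer.forward(h, training=False)
        if i == idx:
            act = h
    logits = h
    gy = np.zeros_like(logits)
    gy[0, target_class] = 1.0
    model.net.zero_grad()
    grad = model.net.backward(gy, stop_at=idx)

    weights = grad.mean(axis=(2, 3))  # (1, maps)
    cam = np.einsum("f,fhw->hw", weights[0], act[0])
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return GradCamMap(heat=cam, target_class=int(target_class),
                      target_layer=target_layer, input_ref=input_ref,
                      n_samples=model.spec.n_samples)


def diff_map(a: GradCamMap, b: GradCamMap) -> np.ndarray:
    """Elementwise ``a - b`` of two normalised maps (range [-1, 1], not
    renormalised); both maps must share shape and input epoch."""
    if a.heat.shape != b.heat.shape:
        raise DimensionError(
            f"heat shapes differ: {a.heat.shape} vs {b.heat.shape}")
    if a.input_ref != b.input_ref:
        raise ConfigurationError(
            f"maps come from different inputs: {a.input_ref!r} vs {b.input_ref!r}")
    return a.heat - b.heat


def heat_mass_fraction(cam: GradCamMap, start_ms: float, end_ms: float,
                       sampling_rate: float) -> float:
    """Fraction of the map's total heat mass inside a time window.

    For a map that is flat in time this equals the window's duration
    fraction; a larger value means the explanation is concentrated in
    the window (time-locality of the class evidence).  Returns 0 for an
    identically zero map.
    """
    heat = cam.resampled()
    total = heat.sum()
    if total == 0:
        return 0.0
    t_ms = np.arange(heat.shape[1]) / sampling_rate * 1000.0
    sel = (t_ms >= start_ms) & (t_ms <= end_ms)
    return float(heat[:, sel].sum() / total)


def overlay(cam: GradCamMap, epoch: np.ndarray, path, sampling_rate: float = 1.0,
            channel_names: list[str] | None = None, dpi: int = 100) -> None:
    """Render the heat map behind the per-channel signal line graph.

    Deterministic for fixed inputs and backend settings (Agg, fixed dpi,
    fixed metadata), so repeated renders are byte-identical.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise DimensionError("overlay expects a (channels, samples) epoch")
    n_ch, n_s = epoch.shape
    heat = cam.resampled(n_s)
    t = np.arange(n_s) / sampling_rate

    fig, ax = plt.subplots(figsize=(8, 4), dpi=dpi)
    ax.imshow(heat, aspect="auto", origin="upper", cmap="inferno",
              vmin=0.0, vmax=1.0, extent=(t[0], t[-1], n_ch - 0.5, -0.5),
              interpolation="nearest")
    span = max(np.abs(epoch).max(), 1e-12)
    for c in range(n_ch):
        ax.plot(t, c - 0.4 * epoch[c] / span, color="w", lw=0.8)
    ax.set_yticks(range(n_ch))
    ax.set_yticklabels(channel_names or [str(c) for c in range(n_ch)])
    ax.set_xlabel("time (s)" if sampling_rate != 1.0 else "sample")
    ax.set_title(f"Grad-CAM @ {cam.target_layer} (class {cam.target_class})")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi, metadata={"Software": "enkit"})
    plt.close(fig)
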