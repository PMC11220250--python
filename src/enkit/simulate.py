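"""Seeded synthetic EEG epoch generator.

Builds labelled multichannel epochs whose class structure lives in
*time-dependent* features, the regime the EnK layer is designed for.
Each epoch is an additive mixture of

* 1/f ("pink") background noise, synthesised by spectral shaping of
  white Gaussian noise and normalised analytically to unit RMS;
* a class-conditional ERP deflection: a Gaussian temporal bump at a
  jittered latency on a subset of electrodes (positive parietal for a
  P300-like task, negative frontal for a cognitive-conflict-like task);
* a band-limited oscillatory burst (Hann-windowed sinusoid with random
  phase, e.g. 10 Hz alpha for motor-imagery-like tasks);
* artifact terms: sporadic large slow blink transients on fronto-polar
  electrodes and a mains-frequency line-noise sinusoid.

Every random draw is taken regardless of the component amplitudes, so
zeroing all amplitudes but one reproduces exactly that component alone
(strict additivity), and a fixed seed gives bit-identical epoch sets.

The container round-trips through HDF5 (``/data`` float32, ``/labels``
int32) with a JSON sidecar carrying sampling metadata and the full
generating spec.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np

from .errors import ConfigurationError

PRESETS = ("p300_like", "conflict_like", "mi_like", "mrcp_like")

# interleaved 10-20 montage so small channel counts still cover frontal,
# central and parietal sites
_MONTAGE = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "Pz",
    "F7", "F8", "Cz", "T7", "T8", "P4", "O1", "O2", "Fz", "P7", "P8",
)


def default_channel_names(n: int) -> list[str]:
    names = list(_MONTAGE[:n])
    names += [f"EXG{i}" for i in range(1, n - len(names) + 1)]
    return names


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------


@dataclass
class BackgroundSpec:
    """1/f noise: PSD ~ f**(-exponent); amplitude is the per-epoch RMS."""

    exponent: float = 1.0
    amplitude: float = 1.0


@dataclass
class ERPSpec:
    """Time-locked Gaussian deflection.

    ``width_ms`` is the Gaussian sigma; latency is jittered uniformly in
    ±``jitter_ms`` per epoch.  ``class_scales`` multiplies the amplitude
    per class (one entry per class), which is how a class-conditional
    ERP — the label-relevant feature — is expressed.
    """

    amplitude: float = 0.0
    latency_ms: float = 300.0
    width_ms: float = 40.0
    sign: int = 1
    jitter_ms: float = 20.0
    channels: tuple[str, ...] = ("P3", "Pz")
    class_scales: tuple[float, ...] = (0.0, 1.0)


@dataclass
class OscillationSpec:
    """Hann-windowed sinusoidal burst with per-epoch random phase and a
    frequency drawn uniformly in ±bandwidth/2 around the center."""

    center_hz: float = 10.0
    bandwidth_hz: float = 2.0
    amplitude: float = 0.0
    burst_start_ms: float = 0.0
    burst_dur_ms: Optional[float] = None  # None = whole epoch
    channels: Optional[tuple[str, ...]] = None  # None = all channels
    class_scales: tuple[float, ...] = (1.0, 1.0)


@dataclass
class ArtifactSpec:
    """Blink transients (slow, large, fronto-polar) and line noise."""

    blink_rate: float = 0.05  # expected blinks per epoch (Poisson)
    blink_amplitude: float = 8.0
    blink_width_ms: float = 75.0
    line_freq_hz: float = 50.0
    line_amplitude: float = 0.2


@dataclass
class SyntheticSpec:
    """Complete recipe for one synthetic epoch set."""

    n_epochs_per_class: int = 200
    n_classes: int = 2
    n_channels: int = 8
    n_samples: int = 128
    sampling_rate: float = 128.0
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    erp: ERPSpec = field(default_factory=ERPSpec)
    oscillation: OscillationSpec = field(default_factory=OscillationSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    class_names: Optional[tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background", "erp", "oscillation", "artifacts"):
            val = getattr(self, name)
            if isinstance(val, dict):
                cls = {"background": BackgroundSpec, "erp": ERPSpec,
                       "oscillation": OscillationSpec, "artifacts": ArtifactSpec}[name]
                setattr(self, name, cls(**val))

    @property
    def epoch_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sampling_rate

    @property
    def class_effect(self) -> dict[str, tuple[float, ...]]:
        """Which components carry the label, via their per-class scales."""
        out = {}
        if self.erp.amplitude != 0 and len(set(self.erp.class_scales)) > 1:
            out["erp"] = self.erp.class_scales
        if self.oscillation.amplitude != 0 and len(set(self.oscillation.class_scales)) > 1:
            out["oscillation"] = self.oscillation.class_scales
        return out

    def validate(self) -> None:
        if self.n_epochs_per_class < 2:
            raise ConfigurationError("need >= 2 epochs per class (stratifiable)")
        if self.n_classes < 2:
            raise ConfigurationError("need >= 2 classes")
        if self.n_channels < 1 or self.n_samples < 1:
            raise ConfigurationError("n_channels and n_samples must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.erp.latency_ms + 3 * self.erp.width_ms > self.epoch_ms:
            raise ConfigurationError(
                f"ERP latency {self.erp.latency_ms} ms + 3*width "
                f"{self.erp.width_ms} ms does not fit in a "
                f"{self.epoch_ms:.0f} ms epoch")
        if self.oscillation.center_hz >= self.sampling_rate / 2:
            raise ConfigurationError(
                f"oscillation {self.oscillation.center_hz} Hz is at or above "
                f"Nyquist ({self.sampling_rate / 2} Hz)")
        for rate in (self.artifacts.blink_rate, self.artifacts.line_amplitude,
                     self.background.amplitude):
            if rate < 0:
                raise ConfigurationError("rates and amplitudes must be >= 0")
        for scales, what in ((self.erp.class_scales, "erp"),
                             (self.oscillation.class_scales, "oscillation")):
            if len(scales) != self.n_classes:
                raise ConfigurationError(
                    f"{what}.class_scales has {len(scales)} entries for "
                    f"{self.n_classes} classes")
        names = default_channel_names(self.n_channels)
        for ch in (self.erp.channels or ()) + (self.oscillation.channels or ()):
            if ch not in names:
                raise ConfigurationError(
                    f"channel {ch!r} not in the {self.n_channels}-channel montage {names}")


@dataclass
class EpochSet:
    """Labelled epoch tensor plus sampling metadata and provenance."""

    data: np.ndarray  # (epochs, channels, samples)
    labels: np.ndarray  # int per epoch
    sampling_rate: float
    channel_names: list[str]
    class_names: list[str]
    provenance: dict

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape[0] != self.data.shape[0]:
            raise ConfigurationError(
                f"{self.labels.shape[0]} labels for {self.data.shape[0]} epochs")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("epoch data contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(self.data[idx], self.labels[idx], self.sampling_rate,
                        list(self.channel_names), list(self.class_names),
                        dict(self.provenance, subset_size=int(len(idx))))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _channel_mask(names: Sequence[str], subset: Optional[Sequence[str]]) -> np.ndarray:
    if subset is None:
        return np.ones(len(names), dtype=bool)
    mask = np.zeros(len(names), dtype=bool)
    for ch in subset:
        mask[list(names).index(ch)] = True
    return mask


def _background(rng: np.random.Generator, E: int, C: int, T: int,
                exponent: float) -> np.ndarray:
    white = rng.standard_normal((E, C, T))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(T)
    f[0] = f[1]  # keep DC finite; it carries negligible power anyway
    shape = f ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shape, n=T, axis=-1)
    # Parseval: white noise has flat unit PSD, so the output RMS is the
    # RMS of the shaping curve (analytic normalisation keeps Gaussianity)
    weights = np.ones_like(shape)
    weights[0] = 0.5
    if T % 2 == 0:
        weights[-1] = 0.5
    rms = np.sqrt(2.0 * np.sum(weights * shape ** 2) / T)
    return shaped / rms


def generate(spec: SyntheticSpec) -> EpochSet:
    """Sample one epoch set from the spec (deterministic per seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    E = spec.n_epochs_per_class * spec.n_classes
    C, T = spec.n_channels, spec.n_samples
    sr = spec.sampling_rate
    t_ms = np.arange(T) / sr * 1000.0
    t_s = np.arange(T) / sr
    names = default_channel_names(C)
    labels = np.repeat(np.arange(spec.n_classes), spec.n_epochs_per_class)

    # every stochastic draw happens unconditionally so the components are
    # strictly additive across amplitude settings
    bg = _background(rng, E, C, T, spec.background.exponent)

    erp = np.zeros((E, C, T))
    e = spec.erp
    erp_mask = _channel_mask(names, e.channels)
    lat = e.latency_ms + rng.uniform(-e.jitter_ms, e.jitter_ms, size=E)
    bump = np.exp(-0.5 * ((t_ms[None, :] - lat[:, None]) / e.width_ms) ** 2)
    scales = np.asarray(e.class_scales)[labels]
    erp[:, erp_mask, :] = (e.sign * scales[:, None] * bump)[:, None, :]

    osc = np.zeros((E, C, T))
    o = spec.oscillation
    osc_mask = _channel_mask(names, o.channels)
    phase = rng.uniform(0, 2 * np.pi, size=E)
    freq = o.center_hz + rng.uniform(-0.5, 0.5, size=E) * o.bandwidth_hz
    dur_ms = o.burst_dur_ms if o.burst_dur_ms is not None else spec.epoch_ms
    u = (t_ms[None, :] - o.burst_start_ms) / dur_ms
    env = np.where((u >= 0) & (u <= 1), np.sin(np.pi * np.clip(u, 0, 1)) ** 2, 0.0)
    wave = env * np.sin(2 * np.pi * freq[:, None] * t_s[None, :] + phase[:, None])
    oscales = np.asarray(o.class_scales)[labels]
    osc[:, osc_mask, :] = (oscales[:, None] * wave)[:, None, :]

    a = spec.artifacts
    blink = np.zeros((E, T))
    n_blinks = rng.poisson(a.blink_rate, size=E)
    for i in range(E):
        for _ in range(n_blinks[i]):
            center = rng.uniform(0, spec.epoch_ms)
            blink[i] += np.exp(-0.5 * ((t_ms - center) / a.blink_width_ms) ** 2)
    frontal = np.array([n.startswith("Fp") for n in names])
    if not frontal.any():
        frontal[0] = True  # degenerate montage: put blinks somewhere frontal-ish
    blinks = np.zeros((E, C, T))
    blinks[:, frontal, :] = blink[:, None, :]

    line_phase = rng.uniform(0, 2 * np.pi, size=E)
    line = np.sin(2 * np.pi * a.line_freq_hz * t_s[None, :] + line_phase[:, None])
    line_full = np.broadcast_to(line[:, None, :], (E, C, T))

    data = (spec.background.amplitude * bg
            + e.amplitude * erp
            + o.amplitude * osc
            + a.blink_amplitude * blinks
            + a.line_amplitude * line_full).astype(np.float32)

    class_names = list(spec.class_names) if spec.class_names else [
        f"class{i}" for i in range(spec.n_classes)]
    return EpochSet(
        data=data, labels=labels, sampling_rate=sr, channel_names=names,
        class_names=class_names,
        provenance={"generator": "enkit.simulate", "spec": asdict(spec),
                    "seed": spec.seed})


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def preset(name: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """Named recipes for the four emulated task families.

    ``p300_like`` — rare-target oddball: positive parietal deflection at
    300 ms on targets only.  ``conflict_like`` — cognitive conflict:
    negative frontal deflection at 200 ms.  ``mi_like`` — motor-imagery:
    class-dependent alpha (10 Hz) burst amplitude over central sites
    (desynchronisation).  ``mrcp_like`` — four-class movement-related
    slow potential over central sites.
    """
    if name == "p300_like":
        spec = SyntheticSpec(
            erp=ERPSpec(amplitude=3.0, latency_ms=300.0, width_ms=40.0, sign=1,
                        jitter_ms=20.0, channels=("P3", "Pz"),
                        class_scales=(0.0, 1.0)),
            oscillation=OscillationSpec(center_hz=10.0, amplitude=0.5),
            class_names=("nontarget", "target"), seed=seed)
    elif name == "conflict_like":
        spec = SyntheticSpec(
            erp=ERPSpec(amplitude=3.0, latency_ms=200.0, width_ms=30.0, sign=-1,
                        jitter_ms=25.0, channels=("Fp1", "Fp2", "F3", "F4"),
                        class_scales=(0.0, 1.0)),
            oscillation=OscillationSpec(center_hz=6.0, amplitude=0.5),
            class_names=("noconflict", "conflict"), seed=seed)
    elif name == "mi_like":
        spec = SyntheticSpec(
            erp=ERPSpec(amplitude=0.0),
            oscillation=OscillationSpec(center_hz=10.0, bandwidth_hz=2.0,
                                        amplitude=1.5, burst_start_ms=250.0,
                                        burst_dur_ms=600.0,
                                        channels=("C3", "C4"),
                                        class_scales=(1.0, 0.35)),
            class_names=("rest", "imagery"), seed=seed)
    elif name == "mrcp_like":
        spec = SyntheticSpec(
            n_classes=4, n_epochs_per_class=100,
            erp=ERPSpec(amplitude=2.5, latency_ms=500.0, width_ms=150.0, sign=-1,
                        jitter_ms=30.0, channels=("C3", "C4"),
                        class_scales=(1.0, 0.5, -0.5, -1.0)),
            oscillation=OscillationSpec(center_hz=2.0, amplitude=0.5,
                                        class_scales=(1.0, 1.0, 1.0, 1.0)),
            class_names=("left_hand", "right_hand", "left_foot", "right_foot"),
            seed=seed)
    else:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESETS}")
    for key, val in overrides.items():
        if not hasattr(spec, key):
            raise ConfigurationError(f"unknown SyntheticSpec field {key!r}")
        setattr(spec, key, val)
    return spec


# ---------------------------------------------------------------------------
# persistence (HDF5 + JSON sidecar)
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_epochs(es: EpochSet, path: str | Path) -> None:
    """Write ``/data`` (float32) and ``/labels`` (int32) plus a JSON
    sidecar with sampling rate, channel/class names and provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=es.data.astype(np.float32))
        h5.create_dataset("labels", data=es.labels.astype(np.int32))
    meta = {
        "sampling_rate": es.sampling_rate,
        "channel_names": list(es.channel_names),
        "class_names": list(es.class_names),
        "provenance": es.provenance,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    if not path.exists():
        raise IOError(f"epoch container {path} does not exist")
    side = _sidecar(path)
    if not side.exists():
        raise IOError(f"missing JSON sidecar {side} for {path}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as err:
        raise IOError(f"corrupt sidecar {side}: {err}") from err
    for key in ("sampling_rate", "channel_names", "class_names", "provenance"):
        if key not in meta:
            raise IOError(f"sidecar {side} missing required key {key!r}")
    try:
        with h5py.File(path, "r") as h5:
            if "data" not in h5 or "labels" not in h5:
                raise IOError(f"{path} missing /data or /labels dataset")
            data = h5["data"][()]
            labels = h5["labels"][()]
    except OSError as err:
        raise IOError(f"corrupt or truncated epoch container {path}: {err}") from err
    return EpochSet(data=data, labels=labels,
                    sampling_rate=meta["sampling_rate"],
                    channel_names=meta["channel_names"],
                    class_names=meta["class_names"],
                    provenance=meta["provenance"])
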