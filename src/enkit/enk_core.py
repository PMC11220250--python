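"""The encoding kernel (EnK): an additive time-decomposition transform.

The EnK treats a windowed multichannel signal as the sum of three
interpretable components, in the spirit of classical additive
time-series decomposition (trend / seasonal / remainder):

* a *periodic* component ``P_t = sin(w_t * x_t + b_t)``, a sine of a
  per-time-step affine map of the signal — sinusoids are the natural
  carrier for the oscillatory structure of EEG (delta through gamma);
* a *seasonal* component ``S_t = (w_t * x_t + b_t) * P_t``, the affine
  term modulated by the periodic one, which reintroduces
  signal-dependent variance that a pure sinusoid cannot express;
* an *artifact* component ``A``, a small learned cross-correlation
  kernel slid over the (channel, time) plane with zero "same" padding,
  playing the role of a band-pass / denoising filter for the very-low
  and high-frequency artifact bands.

The combined output is ``Y_t = P_t + S_t + A_t`` for ``t >= 1`` and the
plain affine pre-activation ``Y_0 = Z_0`` at the first sample.  The
transform is shape-preserving and differentiable, so it can be spliced
into a CNN directly after the first convolution and trained jointly by
backpropagation.  All functions here operate on 4-axis tensors
``(batch, feature_maps, channels, time)`` with time as the last axis;
the per-time-step weights broadcast across the other three axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, DimensionError, SignalValidationError

__all__ = [
    "EnKParams",
    "Decomposition",
    "affine_time",
    "periodic_component",
    "seasonal_component",
    "artifact_component",
    "enk_forward",
    "enk_vjp",
    "init_params",
]


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------


@dataclass
class EnKParams:
    """Trainable parameters of one EnK layer.

    Parameters
    ----------
    w, b
        Per-time-step weight and bias vectors of length ``k`` (the number
        of time samples of the tensor the layer is applied to).  They are
        scalars per time step, broadcast over batch, feature-map and
        channel axes.
    K
        Artifact kernel of shape ``(l, m)`` slid over the
        (channel, time) plane; ``m`` must be odd so zero "same" padding
        is symmetric along time.
    shared_affine
        If True (default) the periodic and seasonal components reuse one
        affine map, the literal reading of the defining equations.  If
        False, ``w_s``/``b_s`` hold a second, independently learned
        affine for the seasonal term.
    trainable
        Whether a host network should update these parameters.
    """

    w: np.ndarray
    b: np.ndarray
    K: np.ndarray
    shared_affine: bool = True
    trainable: bool = True
    w_s: Optional[np.ndarray] = None
    b_s: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.w.ndim != 1 or self.b.ndim != 1:
            raise DimensionError("w and b must be 1-D per-time-step vectors")
        if self.w.shape != self.b.shape:
            raise DimensionError(
                f"w has length {self.w.size} but b has length {self.b.size}"
            )
        if self.K.ndim != 2:
            raise ConfigurationError("artifact kernel K must be a 2-D matrix")
        l, m = self.K.shape
        if l < 1 or m < 1:
            raise ConfigurationError(f"kernel dims must be >= 1, got {l}x{m}")
        if m % 2 == 0:
            raise ConfigurationError(
                f"kernel time width m must be odd for symmetric same-padding, got m={m}"
            )
        if not self.shared_affine:
            if self.w_s is None or self.b_s is None:
                raise ConfigurationError(
                    "shared_affine=False requires separate w_s and b_s vectors"
                )
            self.w_s = np.asarray(self.w_s, dtype=float)
            self.b_s = np.asarray(self.b_s, dtype=float)
            if self.w_s.shape != self.w.shape or self.b_s.shape != self.b.shape:
                raise DimensionError("w_s/b_s must match w/b in length")

    @property
    def k(self) -> int:
        """Number of time samples the affine vectors are sized for."""
        return self.w.size

    @property
    def n_params(self) -> int:
        """Total trainable scalar count: ``2k + l*m`` (``4k + l*m`` unshared)."""
        n = 2 * self.k + self.K.size
        if not self.shared_affine:
            n += 2 * self.k
        return n


@dataclass
class Decomposition:
    """All intermediate tensors of one EnK pass, same shape as the input.

    ``Z`` is the affine pre-activation ``w_t x + b_t``, ``P``/``S``/``A``
    the periodic, seasonal and artifact components, and ``Y`` the
    combined output (``Y_0 = Z_0``; ``Y_t = P_t + S_t + A_t`` for
    ``t >= 1``).  ``Z_s`` is the seasonal pre-activation, identical to
    ``Z`` when the affine is shared.
    """

    Z: np.ndarray
    P: np.ndarray
    S: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    Z_s: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.Z_s is None:
            self.Z_s = self.Z


# ---------------------------------------------------------------------------
# component operations
# ---------------------------------------------------------------------------


def _check_finite(X: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(X)):
        raise SignalValidationError(f"{what} contains non-finite values")


def affine_time(X: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-time-step affine map ``Z[..., t] = w[t] * X[..., t] + b[t]``.

    ``w`` and ``b`` broadcast over every axis except the last (time).
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    b = np.asarray(b, dtype=float)
    k = X.shape[-1]
    if w.shape[-1] != k or b.shape[-1] != k:
        raise DimensionError(
            f"time axis has {k} samples but w has length {w.shape[-1]} "
            f"and b has length {b.shape[-1]}"
        )
    _check_finite(X, "input signal")
    return w * X + b


def periodic_component(Z: np.ndarray) -> np.ndarray:
    """Periodic component ``P = sin(Z)`` elementwise; bounded in [-1, 1]."""
    Z = np.asarray(Z, dtype=float)
    _check_finite(Z, "pre-activation")
    return np.sin(Z)


def seasonal_component(Z: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Seasonal component ``S = Z * P``: the affine term modulated by P.

    Since ``|P| <= 1``, ``|S| <= |Z|`` elementwise — the seasonal term
    never exceeds the pre-activation in magnitude.
    """
    Z = np.asarray(Z, dtype=float)
    P = np.asarray(P, dtype=float)
    if Z.shape != P.shape:
        raise DimensionError(f"Z shape {Z.shape} != P shape {P.shape}")
    return Z * P


def _pad_widths(l: int, m: int) -> tuple[tuple[int, int], tuple[int, int]]:
    pt = (l - 1) // 2
    return (pt, l - 1 - pt), ((m - 1) // 2, (m - 1) // 2)


def _windows(X: np.ndarray, l: int, m: int) -> np.ndarray:
    """Zero-padded sliding (l, m) windows over the trailing two axes."""
    (pt, pb), (pl, pr) = _pad_widths(l, m)
    pad = [(0, 0)] * (X.ndim - 2) + [(pt, pb), (pl, pr)]
    Xp = np.pad(X, pad)
    return sliding_window_view(Xp, (l, m), axis=(-2, -1))


def artifact_component(X: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Artifact component: sliding cross-correlation of X with kernel K.

    The kernel is slid over the (channel, time) plane with zero "same"
    padding and stride 1 (no kernel flip), independently per batch item
    and feature map, so the output shape equals the input shape.
    """
    X = np.asarray(X, dtype=float)
    K = np.asarray(K, dtype=float)
    if K.ndim != 2:
        raise ConfigurationError("artifact kernel must be 2-D")
    l, m = K.shape
    n = X.shape[-2]
    if m % 2 == 0:
        raise ConfigurationError(f"kernel time width must be odd, got m={m}")
    if l > n:
        raise ConfigurationError(
            f"kernel has {l} channel rows but the signal only {n} channels"
        )
    win = _windows(X, l, m)  # (..., n, k, l, m)
    return np.einsum("...lm,lm->...", win, K)


def enk_forward(X: np.ndarray, params: EnKParams) -> Decomposition:
    """Full EnK pass returning every component for inspection.

    ``Y[..., 0] = Z[..., 0]`` (the first sample receives the plain
    affine only) and ``Y[..., t] = P + S + A`` for ``t >= 1``.
    """
    X = np.asarray(X, dtype=float)
    k = X.shape[-1]
    if params.k != k:
        raise DimensionError(
            f"params sized for k={params.k} time samples, input has k={k}"
        )
    Z = affine_time(X, params.w, params.b)
    P = periodic_component(Z)
    if params.shared_affine:
        Z_s = Z
    else:
        Z_s = affine_time(X, params.w_s, params.b_s)
    S = seasonal_component(Z_s, P)
    A = artifact_component(X, params.K)
    Y = P + S + A
    Y[..., 0] = Z[..., 0]
    return Decomposition(Z=Z, P=P, S=S, A=A, Y=Y, Z_s=Z_s)


def enk_vjp(
    X: np.ndarray,
    params: EnKParams,
    decomp: Decomposition,
    gY: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vector-Jacobian product of ``enk_forward`` for backpropagation.

    Given the upstream gradient ``gY`` (d loss / d Y), returns gradients
    with respect to the input ``X`` and every parameter, derived
    analytically:

    * for ``t >= 1`` the periodic pre-activation carries
      ``dY/dZ = cos(Z) * (1 + Z_s)`` (through ``P`` directly and through
      ``S = Z_s * P``), and the seasonal pre-activation carries
      ``dY/dZ_s = P``; with a shared affine the two sum;
    * at ``t = 0`` the output is ``Z_0`` so only the affine path carries
      gradient (the artifact path is masked there).
    """
    Z, P, Z_s = decomp.Z, decomp.P, decomp.Z_s
    sum_axes = tuple(range(gY.ndim - 1))  # all but time

    cosZ = np.cos(Z)
    # periodic path: Y <- P and Y <- S = Z_s * P, both via Z
    dY_dZ = cosZ + Z_s * cosZ
    gZ = gY * dY_dZ
    gZ[..., 0] = gY[..., 0]  # t=0 branch: Y_0 = Z_0
    # seasonal pre-activation path: Y <- S = Z_s * P
    gZ_s = gY * P
    gZ_s[..., 0] = 0.0

    if params.shared_affine:
        gZ_total = gZ + gZ_s
        gw = np.sum(gZ_total * X, axis=sum_axes)
        gb = np.sum(gZ_total, axis=sum_axes)
        gX = gZ_total * params.w
        grads = {"w": gw, "b": gb}
    else:
        gw = np.sum(gZ * X, axis=sum_axes)
        gb = np.sum(gZ, axis=sum_axes)
        gws = np.sum(gZ_s * X, axis=sum_axes)
        gbs = np.sum(gZ_s, axis=sum_axes)
        gX = gZ * params.w + gZ_s * params.w_s
        grads = {"w": gw, "b": gb, "w_s": gws, "b_s": gbs}

    # artifact path (masked at t=0)
    K = params.K
    l, m = K.shape
    gA = gY.copy()
    gA[..., 0] = 0.0
    win = _windows(X, l, m)
    grads["K"] = np.einsum("xlm,x->lm", win.reshape(-1, l, m), gA.reshape(-1))

    # dA/dX: full correlation of gA with the doubly flipped kernel,
    # cropped to undo the forward same-padding.
    n, k = X.shape[-2], X.shape[-1]
    (pt, _pb), (pl, _pr) = _pad_widths(l, m)
    pad = [(0, 0)] * (gA.ndim - 2) + [(l - 1, l - 1), (m - 1, m - 1)]
    gAp = np.pad(gA, pad)
    winb = sliding_window_view(gAp, (l, m), axis=(-2, -1))
    gXp = np.einsum("...lm,lm->...", winb, K[::-1, ::-1])
    gX = gX + gXp[..., pt : pt + n, pl : pl + k]

    grads["X"] = gX
    return grads


def init_params(
    n: int,
    k: int,
    l: int = 1,
    m: int = 7,
    seed: Optional[int] = None,
    shared_affine: bool = True,
    randomized: bool = False,
    init_scale: float = 0.1,
) -> EnKParams:
    """Near-pass-through initialisation of an EnK layer.

    ``w`` starts at all-ones, ``b`` at all-zeros and ``K`` at the
    uniform averaging kernel ``1/(l*m)``, so an untrained layer
    perturbs its host network minimally (``P+S+A`` of a small signal is
    close to a smoothed copy of it).  Deterministic for fixed
    arguments; with ``randomized=True`` a seeded Gaussian perturbation
    of scale ``init_scale`` is added.
    """
    if k < 1:
        raise ConfigurationError(f"need at least one time sample, got k={k}")
    if n < 1:
        raise ConfigurationError(f"need at least one channel, got n={n}")
    if l < 1 or m < 1:
        raise ConfigurationError(f"kernel dims must be >= 1, got {l}x{m}")
    if m % 2 == 0:
        raise ConfigurationError(f"kernel time width must be odd, got m={m}")
    if l > n:
        raise ConfigurationError(f"kernel rows l={l} exceed channel count n={n}")
    w = np.ones(k)
    b = np.zeros(k)
    K = np.full((l, m), 1.0 / (l * m))
    if randomized:
        rng = np.random.default_rng(seed)
        w = w + init_scale * rng.standard_normal(k)
        b = b + init_scale * rng.standard_normal(k)
        K = K + init_scale / (l * m) * rng.standard_normal((l, m))
    extra = {}
    if not shared_affine:
        extra = {"w_s": w.copy(), "b_s": b.copy()}
    return EnKParams(w=w, b=b, K=K, shared_affine=shared_affine, **extra)
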