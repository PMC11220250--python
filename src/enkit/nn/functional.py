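"""Stateless forward/backward primitives for the numpy network engine.

Every function returns the forward output together with a cache tuple
that its matching ``*_backward`` consumes, so composite layers (e.g. a
recurrent convolution applied several times with shared weights) can
call the same primitive repeatedly without clobbering layer state.

Tensor layout is ``(batch, maps, height, width)`` throughout; for EEG
epochs height is the electrode axis and width the time axis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import DimensionError

Cache = tuple


def _same_pad(k: int) -> tuple[int, int]:
    # asymmetric for even kernels, matching the usual deep-learning rule
    return ((k - 1) // 2, k - 1 - (k - 1) // 2)


def pad_for(kh: int, kw: int, padding: str) -> tuple[tuple[int, int], tuple[int, int]]:
    if padding == "valid":
        return (0, 0), (0, 0)
    if padding == "same":
        return _same_pad(kh), _same_pad(kw)
    raise ValueError(f"unknown padding {padding!r}")


def _im2col(xp: np.ndarray, kh: int, kw: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Padded input (B,Ci,Hp,Wp) -> contiguous (B, Ci*kh*kw, Ho*Wo) columns."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,Ci,Ho,Wo,kh,kw)
    B, Ci, Ho, Wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))
    return cols.reshape(B, Ci * kh * kw, Ho * Wo), (Ho, Wo)


def _col2im(gcols: np.ndarray, padded_shape: tuple[int, ...], kh: int, kw: int,
            Ho: int, Wo: int) -> np.ndarray:
    """Scatter-add stride-1 columns back onto the padded input plane."""
    B, Ckk, _ = gcols.shape
    Ci = Ckk // (kh * kw)
    g6 = gcols.reshape(B, Ci, kh, kw, Ho, Wo)
    gxp = np.zeros(padded_shape, dtype=gcols.dtype)
    for u in range(kh):
        for v in range(kw):
            gxp[:, :, u : u + Ho, v : v + Wo] += g6[:, :, u, v]
    return gxp


def conv2d_forward(
    x: np.ndarray, W: np.ndarray, b: np.ndarray | None, padding: str
) -> tuple[np.ndarray, Cache]:
    """Cross-correlation of ``x`` (B,Ci,H,Wd) with ``W`` (Co,Ci,kh,kw)."""
    co, ci, kh, kw = W.shape
    (pt, pb), (pl, pr) = pad_for(kh, kw, padding)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    if xp.shape[2] < kh or xp.shape[3] < kw:
        raise DimensionError(
            f"input plane {x.shape[2]}x{x.shape[3]} too small for "
            f"{kh}x{kw} kernel with {padding} padding"
        )
    cols, (Ho, Wo) = _im2col(xp, kh, kw)
    y = np.matmul(W.reshape(co, -1)[None], cols).reshape(x.shape[0], co, Ho, Wo)
    if b is not None:
        y = y + b[None, :, None, None]
    return y, (x.shape, xp.shape, cols, W, b is not None, (pt, pl), (Ho, Wo))


def conv2d_backward(gy: np.ndarray, cache: Cache) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    x_shape, xp_shape, cols, W, has_bias, (pt, pl), (Ho, Wo) = cache
    co, ci, kh, kw = W.shape
    B = gy.shape[0]
    gy2 = gy.reshape(B, co, Ho * Wo)
    gW = np.matmul(gy2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(W.shape)
    gb = gy.sum(axis=(0, 2, 3)) if has_bias else None
    gcols = np.matmul(W.reshape(co, -1).T[None], gy2)
    gxp = _col2im(gcols, xp_shape, kh, kw, Ho, Wo)
    H, Wd = x_shape[2], x_shape[3]
    gx = gxp[:, :, pt : pt + H, pl : pl + Wd]
    return gx, gW, gb


def depthwise_conv2d_forward(
    x: np.ndarray, W: np.ndarray, padding: str
) -> tuple[np.ndarray, Cache]:
    """Depthwise cross-correlation; ``W`` is (Ci, D, kh, kw), output (B, Ci*D, ...)."""
    ci, d, kh, kw = W.shape
    (pt, pb), (pl, pr) = pad_for(kh, kw, padding)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    if xp.shape[2] < kh or xp.shape[3] < kw:
        raise DimensionError(
            f"input plane {x.shape[2]}x{x.shape[3]} too small for depthwise "
            f"{kh}x{kw} kernel with {padding} padding"
        )
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,Ci,Ho,Wo,kh,kw)
    y = np.einsum("bihwkl,idkl->bidhw", win, W, optimize=True)
    B, _, Ho, Wo = y.shape[0], y.shape[1], y.shape[3], y.shape[4]
    y = y.reshape(B, ci * d, Ho, Wo)
    return y, (x.shape, win, W, (pt, pl))


def depthwise_conv2d_backward(gy: np.ndarray, cache: Cache) -> tuple[np.ndarray, np.ndarray]:
    x_shape, win, W, (pt, pl) = cache
    ci, d, kh, kw = W.shape
    B = gy.shape[0]
    gy5 = gy.reshape(B, ci, d, gy.shape[2], gy.shape[3])
    gW = np.einsum("bihwkl,bidhw->idkl", win, gy5, optimize=True)
    gyp = np.pad(gy5, ((0, 0), (0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    winb = sliding_window_view(gyp, (kh, kw), axis=(3, 4))  # (B,Ci,D,Hp,Wp,kh,kw)
    gxp = np.einsum("bidhwkl,idkl->bihw", winb, W[:, :, ::-1, ::-1], optimize=True)
    H, Wd = x_shape[2], x_shape[3]
    gx = gxp[:, :, pt : pt + H, pl : pl + Wd]
    return gx, gW


def _pool_windows(x: np.ndarray, pool: tuple[int, int], stride: tuple[int, int]) -> np.ndarray:
    ph, pw = pool
    sh, sw = stride
    if x.shape[2] < ph or x.shape[3] < pw:
        raise DimensionError(
            f"input plane {x.shape[2]}x{x.shape[3]} too small for {ph}x{pw} pooling"
        )
    win = sliding_window_view(x, (ph, pw), axis=(2, 3))
    return win[:, :, ::sh, ::sw]


def avg_pool2d_forward(
    x: np.ndarray, pool: tuple[int, int], stride: tuple[int, int]
) -> tuple[np.ndarray, Cache]:
    win = _pool_windows(x, pool, stride)
    y = win.mean(axis=(-2, -1))
    return y, (x.shape, pool, stride, y.shape)


def avg_pool2d_backward(gy: np.ndarray, cache: Cache) -> np.ndarray:
    x_shape, (ph, pw), (sh, sw), y_shape = cache
    gx = np.zeros(x_shape, dtype=gy.dtype)
    g = gy / (ph * pw)
    Ho, Wo = y_shape[2], y_shape[3]
    # windows may overlap (stride < pool); within one (u, v) offset the
    # target positions are distinct, so strided += is safe
    for u in range(ph):
        for v in range(pw):
            gx[:, :, u : u + sh * Ho : sh, v : v + sw * Wo : sw] += g
    return gx


def max_pool2d_forward(
    x: np.ndarray, pool: tuple[int, int], stride: tuple[int, int]
) -> tuple[np.ndarray, Cache]:
    win = _pool_windows(x, pool, stride)
    B, C, Ho, Wo = win.shape[:4]
    flat = win.reshape(B, C, Ho, Wo, -1)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, (x.shape, pool, stride, idx)


def max_pool2d_backward(gy: np.ndarray, cache: Cache) -> np.ndarray:
    x_shape, (ph, pw), (sh, sw), idx = cache
    B, C, Ho, Wo = idx.shape
    gx = np.zeros(x_shape, dtype=gy.dtype)
    bb, cc, hh, ww = np.ix_(np.arange(B), np.arange(C), np.arange(Ho), np.arange(Wo))
    h = hh * sh + idx // pw
    w = ww * sw + idx % pw
    np.add.at(gx, (bb, cc, h, w), gy)
    return gx
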