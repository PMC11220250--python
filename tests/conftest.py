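"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

from enkit.enk_core import EnKParams
from enkit.simulate import SyntheticSpec, ERPSpec, OscillationSpec, generate


def enk_scalar_oracle(X: np.ndarray, params: EnKParams) -> np.ndarray:
    """Independent scalar-loop implementation of the EnK transform.

    Literal elementwise translation of the defining equations: affine,
    sine, product, windowed kernel sum with zero padding, and the t=0
    branch.  Deliberately unvectorised so it shares no code path with
    ``enk_forward``.
    """
    B, F, n, k = X.shape
    l, m = params.K.shape
    pt, pl = (l - 1) // 2, (m - 1) // 2
    w, b, K = params.w, params.b, params.K
    if params.shared_affine:
        ws, bs = w, b
    else:
        ws, bs = params.w_s, params.b_s
    Y = np.empty_like(X, dtype=float)
    for bi in range(B):
        for fi in range(F):
            for c in range(n):
                for t in range(k):
                    z = w[t] * X[bi, fi, c, t] + b[t]
                    if t == 0:
                        Y[bi, fi, c, t] = z
                        continue
                    p = math.sin(z)
                    s = (ws[t] * X[bi, fi, c, t] + bs[t]) * p
                    a = 0.0
                    for i in range(l):
                        for j in range(m):
                            cc = c + i - pt
                            tt = t + j - pl
                            if 0 <= cc < n and 0 <= tt < k:
                                a += X[bi, fi, cc, tt] * K[i, j]
                    Y[bi, fi, c, t] = p + s + a
    return Y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_epochs():
    """Small, fast, clearly separable two-class epoch set (40 epochs)."""
    spec = SyntheticSpec(
        n_epochs_per_class=20, n_channels=4, n_samples=64, sampling_rate=64,
        erp=ERPSpec(amplitude=4.0, latency_ms=400.0, width_ms=80.0,
                    jitter_ms=10.0, channels=("F3", "F4"),
                    class_scales=(0.0, 1.0)),
        oscillation=OscillationSpec(amplitude=0.3, center_hz=10.0),
        seed=99)
    return generate(spec)
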