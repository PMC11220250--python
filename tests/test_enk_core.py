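"""Unit and property tests for the EnK decomposition core."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from enkit import enk_core as ec
from enkit.errors import ConfigurationError, DimensionError, SignalValidationError

from conftest import enk_scalar_oracle


def _params(n, k, l=1, m=1, seed=None, randomized=False, shared=True):
    return ec.init_params(n=n, k=k, l=l, m=m, seed=seed,
                          randomized=randomized, shared_affine=shared)


class TestAffineTime:
    @pytest.mark.parametrize("x,w,b,expected", [
        ([1.0, 2.0], [1, 1], [0, 0], [1.0, 2.0]),
        ([5.0, 7.0], [0, 0], [3, 3], [3.0, 3.0]),
        ([1.0, 2.0], [2, 3], [1, -1], [3.0, 5.0]),
    ])
    def test_examples(self, x, w, b, expected):
        np.testing.assert_allclose(ec.affine_time(np.array(x), w, b), expected)

    def test_broadcasts_over_leading_axes(self, rng):
        X = rng.standard_normal((2, 3, 4, 5))
        w, b = rng.standard_normal(5), rng.standard_normal(5)
        Z = ec.affine_time(X, w, b)
        assert Z.shape == X.shape
        np.testing.assert_allclose(Z[1, 2, 3], w * X[1, 2, 3] + b)

    def test_length_mismatch_names_both_lengths(self):
        with pytest.raises(DimensionError, match="5.*3|3.*5"):
            ec.affine_time(np.zeros(5), np.ones(3), np.zeros(3))

    def test_rejects_non_finite(self):
        with pytest.raises(SignalValidationError):
            ec.affine_time(np.array([1.0, np.nan]), [1, 1], [0, 0])


class TestComponents:
    @pytest.mark.parametrize("z,expected", [
        (0.0, 0.0), (np.pi / 2, 1.0), (2.0, np.sin(2.0))])
    def test_periodic_values(self, z, expected):
        assert ec.periodic_component(np.array(z)) == pytest.approx(expected)

    def test_periodic_rejects_non_finite(self):
        with pytest.raises(SignalValidationError):
            ec.periodic_component(np.array([np.inf]))

    @pytest.mark.parametrize("z,p,expected", [
        (0.0, 0.0, 0.0),
        (np.pi / 2, 1.0, np.pi / 2),
        (2.0, np.sin(2.0), 2.0 * np.sin(2.0)),  # 1.8185948536...
    ])
    def test_seasonal_values(self, z, p, expected):
        assert ec.seasonal_component(np.array(z), np.array(p)) == pytest.approx(expected)

    def test_seasonal_shape_mismatch(self):
        with pytest.raises(DimensionError):
            ec.seasonal_component(np.zeros(3), np.zeros(4))


class TestArtifact:
    def test_identity_kernel(self, rng):
        X = rng.standard_normal((2, 1, 3, 5))
        np.testing.assert_allclose(ec.artifact_component(X, np.array([[1.0]])), X)

    def test_averaging_preserves_constants_in_interior(self):
        X = np.full((1, 1, 1, 9), 4.2)
        A = ec.artifact_component(X, np.full((1, 3), 1 / 3))
        np.testing.assert_allclose(A[..., 1:-1], 4.2)

    def test_sliding_sum_with_zero_padding(self):
        A = ec.artifact_component(np.array([[1.0, 2.0, 3.0]]),
                                  np.array([[1.0, 1.0, 1.0]]))
        np.testing.assert_allclose(A, [[3.0, 6.0, 5.0]])

    def test_matches_scipy_correlate2d(self, rng):
        from scipy.signal import correlate2d
        X = rng.standard_normal((4, 7))
        K = rng.standard_normal((3, 5))
        expected = correlate2d(X, K, mode="same", boundary="fill")
        np.testing.assert_allclose(ec.artifact_component(X, K), expected,
                                   atol=1e-12)

    def test_even_kernel_width_rejected(self):
        with pytest.raises(ConfigurationError, match="odd"):
            ec.artifact_component(np.zeros((2, 4)), np.ones((1, 2)))

    def test_kernel_taller_than_channels_rejected(self):
        with pytest.raises(ConfigurationError, match="channel"):
            ec.artifact_component(np.zeros((2, 4)), np.ones((3, 1)))


class TestEnkForward:
    def test_scalar_worked_example(self):
        p = _params(n=1, k=2)
        d = ec.enk_forward(np.array([[1.0, 2.0]]), p)
        np.testing.assert_allclose(d.Y, [[1.0, 3.0 * np.sin(2.0) + 2.0]])

    def test_zero_parameter_limit(self, rng):
        X = rng.standard_normal((2, 3, 4, 6))
        p = _params(n=4, k=6)
        p.w[:] = 0.0
        d = ec.enk_forward(X, p)
        np.testing.assert_array_equal(d.Y[..., 0], 0.0)
        np.testing.assert_array_equal(d.Y[..., 1:], d.A[..., 1:])
        # with the identity-sized averaging kernel (l=m=1), A = X exactly
        np.testing.assert_allclose(d.A, X)

    def test_shape_preserved(self, rng):
        X = rng.standard_normal((2, 4, 8, 16))
        p = _params(n=8, k=16, l=3, m=7, randomized=True, seed=5)
        assert ec.enk_forward(X, p).Y.shape == (2, 4, 8, 16)

    def test_additive_identity_for_t_ge_1(self, rng):
        X = rng.standard_normal((1, 2, 3, 8))
        p = _params(n=3, k=8, l=2, m=3, randomized=True, seed=2)
        d = ec.enk_forward(X, p)
        np.testing.assert_array_equal(d.Y[..., 1:],
                                      (d.P + d.S + d.A)[..., 1:])
        np.testing.assert_array_equal(d.Y[..., 0], d.Z[..., 0])

    def test_params_length_mismatch(self, rng):
        with pytest.raises(DimensionError):
            ec.enk_forward(rng.standard_normal((1, 1, 2, 5)), _params(n=2, k=4))

    @pytest.mark.parametrize("shared", [True, False])
    def test_matches_scalar_oracle(self, shared):
        rng = np.random.default_rng(777)
        for trial in range(100):
            B, F = rng.integers(1, 5), rng.integers(1, 5)
            n, k = rng.integers(1, 9), rng.integers(1, 17)
            l = int(rng.integers(1, min(n, 3) + 1))
            m = int(rng.choice([1, 3, 5, 7]))
            X = rng.standard_normal((B, F, n, k))
            p = _params(n=n, k=k, l=l, m=m, randomized=True,
                        seed=int(rng.integers(0, 2 ** 31)), shared=shared)
            got = ec.enk_forward(X, p).Y
            expected = enk_scalar_oracle(X, p)
            np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((2, 2, 3, 5))
        p = _params(n=3, k=5, l=2, m=3, randomized=True, seed=4)
        gY = rng.standard_normal(X.shape)
        d = ec.enk_forward(X, p)
        g = ec.enk_vjp(X, p, d, gY)
        eps = 1e-6

        def loss(Xv, pv):
            return float((ec.enk_forward(Xv, pv).Y * gY).sum())

        for name in ("w", "b", "K"):
            arr = getattr(p, name)
            for idx in np.ndindex(*arr.shape):
                pp, pm = copy.deepcopy(p), copy.deepcopy(p)
                getattr(pp, name)[idx] += eps
                getattr(pm, name)[idx] -= eps
                num = (loss(X, pp) - loss(X, pm)) / (2 * eps)
                denom = max(abs(num), 1.0)
                assert abs(num - g[name][idx]) / denom < 1e-4
        num_x = np.zeros_like(X)
        for idx in np.ndindex(*X.shape):
            Xp, Xm = X.copy(), X.copy()
            Xp[idx] += eps
            Xm[idx] -= eps
            num_x[idx] = (loss(Xp, p) - loss(Xm, p)) / (2 * eps)
        np.testing.assert_allclose(g["X"], num_x, rtol=1e-4, atol=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(hnp.arrays(np.float64, hnp.array_shapes(min_dims=4, max_dims=4,
                                               min_side=1, max_side=6),
                  elements=st.floats(-50, 50)))
def test_boundedness_invariants(X):
    """P stays in [-1, 1] and |S| <= |Z| for arbitrary finite inputs."""
    n, k = X.shape[-2], X.shape[-1]
    p = ec.init_params(n=n, k=k, l=1, m=1, randomized=True, seed=1)
    d = ec.enk_forward(X, p)
    assert np.all(d.P >= -1.0) and np.all(d.P <= 1.0)
    assert np.all(np.abs(d.S) <= np.abs(d.Z) + 1e-12)
    assert d.Y.shape == X.shape


class TestInitParams:
    def test_stated_defaults(self):
        p = ec.init_params(n=8, k=16, l=1, m=7)
        np.testing.assert_array_equal(p.w, np.ones(16))
        np.testing.assert_array_equal(p.b, np.zeros(16))
        np.testing.assert_allclose(p.K, np.full((1, 7), 1 / 7))

    def test_parameter_count(self):
        assert ec.init_params(n=8, k=16, l=1, m=7).n_params == 2 * 16 + 7

    def test_deterministic(self):
        a = ec.init_params(n=4, k=8, l=2, m=3, seed=9, randomized=True)
        b = ec.init_params(n=4, k=8, l=2, m=3, seed=9, randomized=True)
        np.testing.assert_array_equal(a.w, b.w)
        np.testing.assert_array_equal(a.K, b.K)

    @pytest.mark.parametrize("kwargs", [
        dict(n=4, k=0), dict(n=0, k=4), dict(n=4, k=4, m=4),
        dict(n=4, k=4, l=0), dict(n=2, k=4, l=3)])
    def test_invalid_dimensions(self, kwargs):
        with pytest.raises(ConfigurationError):
            ec.init_params(**kwargs)
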