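"""Gradient correctness of the autodiff core against central differences."""

import numpy as np
import pytest

import cascadereg.autodiff as ad


def weighted_sum(t, w):
    """Scalar probe sum(w * t) as a graph op, for gradient checks."""
    out = ad._make(np.float32((t.data * w).sum()), (t,))

    def back(g):
        t._accumulate(g * w)
    out._backward = back
    return out


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros(x.shape, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_matches(build, tensors, tol=2e-2):
    for t in tensors:
        t.grad = None
    build().backward()
    for t in tensors:
        analytic = t.grad.copy()
        numeric = numeric_grad(lambda: build().item(), t.data)
        scale = np.abs(numeric).max() + 1e-8
        assert np.max(np.abs(analytic - numeric)) / scale < tol


@pytest.fixture
def arng():
    return np.random.default_rng(42)


class TestConvOps:
    def test_conv3d_gradients(self, arng):
        x = ad.Tensor(arng.normal(size=(2, 5, 5, 5)).astype(np.float32),
                      requires_grad=True)
        W = ad.Parameter(arng.normal(size=(3, 2, 3, 3, 3)).astype(np.float32)
                         * 0.3)
        b = ad.Parameter(arng.normal(size=3).astype(np.float32))
        w = arng.normal(size=(3, 3, 3, 3)).astype(np.float32)
        assert_grad_matches(
            lambda: weighted_sum(ad.conv3d(x, W, b, stride=2, pad=1), w),
            [x, W, b])

    def test_conv3d_stride1_gradients(self, arng):
        x = ad.Tensor(arng.normal(size=(1, 4, 4, 4)).astype(np.float32),
                      requires_grad=True)
        W = ad.Parameter(arng.normal(size=(2, 1, 3, 3, 3)).astype(np.float32)
                         * 0.3)
        b = ad.Parameter(np.zeros(2, dtype=np.float32))
        w = arng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        assert_grad_matches(
            lambda: weighted_sum(ad.conv3d(x, W, b, stride=1, pad=1), w),
            [x, W, b])

    def test_conv_transpose_gradients_and_shape(self, arng):
        x = ad.Tensor(arng.normal(size=(3, 3, 3, 3)).astype(np.float32),
                      requires_grad=True)
        W = ad.Parameter(arng.normal(size=(3, 2, 4, 4, 4)).astype(np.float32)
                         * 0.2)
        b = ad.Parameter(arng.normal(size=2).astype(np.float32))
        y = ad.conv_transpose3d(x, W, b, stride=2, pad=1)
        assert y.shape == (2, 6, 6, 6)  # exact doubling for k=4, s=2, p=1
        w = arng.normal(size=(2, 6, 6, 6)).astype(np.float32)
        assert_grad_matches(
            lambda: weighted_sum(ad.conv_transpose3d(x, W, b), w), [x, W, b])

    def test_conv_transpose_is_conv_adjoint(self, arng):
        """<conv(x), y> == <x, convT(y)> for matching shapes."""
        W = arng.normal(size=(2, 3, 4, 4, 4)).astype(np.float32)
        x = arng.normal(size=(3, 6, 6, 6)).astype(np.float32)
        y = arng.normal(size=(2, 3, 3, 3)).astype(np.float32)
        zb = ad.Tensor(np.zeros(2, dtype=np.float32))
        zb3 = ad.Tensor(np.zeros(3, dtype=np.float32))
        cx = ad.conv3d(ad.Tensor(x), ad.Tensor(W), zb, stride=2, pad=1).data
        cty = ad.conv_transpose3d(ad.Tensor(y), ad.Tensor(W), zb3,
                                  stride=2, pad=1).data
        assert np.allclose((cx * y).sum(), (x * cty).sum(), rtol=1e-4)


class TestPointwiseOps:
    def test_linear_and_slice(self, arng):
        x = ad.Tensor(arng.normal(size=6).astype(np.float32),
                      requires_grad=True)
        W = ad.Parameter(arng.normal(size=(12, 6)).astype(np.float32))
        b = ad.Parameter(arng.normal(size=12).astype(np.float32))
        w = arng.normal(size=(3, 3)).astype(np.float32)
        assert_grad_matches(
            lambda: weighted_sum(
                ad.slice_vector(ad.linear(x, W, b), 0, 9, (3, 3)), w),
            [x, W, b])

    def test_leaky_relu_gradient(self, arng):
        x = ad.Tensor(arng.normal(size=(2, 3, 3, 3)).astype(np.float32),
                      requires_grad=True)
        w = arng.normal(size=(2, 3, 3, 3)).astype(np.float32)
        assert_grad_matches(
            lambda: weighted_sum(ad.leaky_relu(x, 0.1), w), [x])

    def test_concat_splits_gradient(self, arng):
        a = ad.Tensor(arng.normal(size=(1, 2, 2, 2)).astype(np.float32),
                      requires_grad=True)
        b = ad.Tensor(arng.normal(size=(2, 2, 2, 2)).astype(np.float32),
                      requires_grad=True)
        w = arng.normal(size=(3, 2, 2, 2)).astype(np.float32)
        assert_grad_matches(
            lambda: weighted_sum(ad.concat_channels(a, b), w), [a, b])


class TestGridSample:
    def test_gradients_both_arguments(self, arng):
        img = ad.Tensor(arng.normal(size=(2, 6, 6, 6)).astype(np.float32),
                        requires_grad=True)
        # keep sample points away from integer coordinates, where trilinear
        # interpolation is only subdifferentiable
        disp = ad.Tensor(arng.uniform(0.25, 0.65, size=(3, 6, 6, 6))
                         .astype(np.float32), requires_grad=True)
        w = arng.normal(size=(2, 6, 6, 6)).astype(np.float32)
        assert_grad_matches(
            lambda: weighted_sum(ad.grid_sample(img, disp), w), [img, disp])

    def test_zero_displacement_is_exact_identity(self, arng):
        img = ad.Tensor(arng.random(size=(1, 5, 5, 5)).astype(np.float32))
        disp = ad.Tensor(np.zeros((3, 5, 5, 5), dtype=np.float32))
        out = ad.grid_sample(img, disp)
        assert np.array_equal(out.data, img.data)


class TestLossOps:
    def test_cc_loss_gradient(self, arng):
        fixed = arng.normal(size=(5, 5, 5)).astype(np.float32)
        warped = ad.Tensor(arng.normal(size=(5, 5, 5)).astype(np.float32),
                           requires_grad=True)
        assert_grad_matches(lambda: ad.cc_loss(fixed, warped), [warped],
                            tol=5e-2)

    def test_affine_loss_gradients(self, arng):
        A = ad.Tensor((arng.normal(size=(3, 3)) * 0.1).astype(np.float32),
                      requires_grad=True)
        assert_grad_matches(lambda: ad.orthogonality_loss_t(A), [A])
        assert_grad_matches(lambda: ad.determinant_loss_t(A), [A])

    def test_field_loss_gradients(self, arng):
        u = ad.Tensor((arng.normal(size=(3, 5, 5, 5)) * 0.5)
                      .astype(np.float32), requires_grad=True)
        assert_grad_matches(lambda: ad.smoothness_loss_t(u), [u])
        assert_grad_matches(lambda: ad.topology_loss_t(u), [u])

    def test_affine_field_gradients(self, arng):
        A = ad.Tensor((arng.normal(size=(3, 3)) * 0.1).astype(np.float32),
                      requires_grad=True)
        b = ad.Tensor(arng.normal(size=3).astype(np.float32),
                      requires_grad=True)
        w = arng.normal(size=(3, 4, 4, 4)).astype(np.float32)
        assert_grad_matches(
            lambda: weighted_sum(ad.affine_field(A, b, (4, 4, 4)), w), [A, b])

    def test_tensor_values_match_numpy_losses(self, arng):
        """The differentiable losses agree with the reference implementations."""
        from cascadereg.deform import AffineParams, DisplacementField
        from cascadereg import losses
        u = (arng.normal(size=(3, 6, 6, 6)) * 0.8).astype(np.float32)
        f = DisplacementField(u)
        assert ad.smoothness_loss_t(ad.Tensor(u)).item() == pytest.approx(
            losses.smoothness_loss(f), rel=1e-5)
        assert ad.topology_loss_t(ad.Tensor(u)).item() == pytest.approx(
            losses.topology_loss(f), rel=1e-5, abs=1e-7)
        A = (arng.normal(size=(3, 3)) * 0.1).astype(np.float32)
        p = AffineParams(A, np.zeros(3))
        assert ad.orthogonality_loss_t(ad.Tensor(A)).item() == pytest.approx(
            losses.orthogonality_loss(p), rel=1e-4)
        a = arng.random(size=(6, 6, 6)).astype(np.float32)
        b = arng.random(size=(6, 6, 6)).astype(np.float32)
        assert ad.cc_loss(a, ad.Tensor(b)).item() == pytest.approx(
            losses.similarity_loss(a, b), rel=1e-4)


class TestAdam:
    def test_minimizes_quadratic(self):
        p = ad.Parameter(np.array([3.0, -2.0], dtype=np.float32))
        opt = ad.Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            p.grad = 2 * p.data  # d/dp sum(p^2)
            opt.step()
        assert np.abs(p.data).max() < 1e-2
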