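"""Minimal reverse-mode automatic differentiation core (CPU, numpy).

Implements exactly the operations the cascade networks and their losses
need: 3D convolution and transposed convolution (im2col + GEMM), a fully
connected layer, LeakyReLU, channel concatenation, differentiable trilinear
grid sampling (gradients with respect to both the sampled image and the
displacement field), and analytic-gradient versions of every loss term.
Everything is float32 and fully deterministic.

Gradients of every op are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import warnings

import numpy as np


class Tensor:
    """A numpy array plus a backward closure for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float32)
        self.grad += g.astype(np.float32)

    def backward(self) -> None:
        """Backpropagate from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # scalar algebra (used to combine loss terms)
    def __add__(self, other: "Tensor") -> "Tensor":
        out = _make(self.data + other.data, (self, other))
        def back(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)
        out._backward = back
        return out

    def __mul__(self, c: float) -> "Tensor":
        c = float(c)
        out = _make(self.data * c, (self,))
        def back(g):
            if self.requires_grad:
                self._accumulate(g * c)
        out._backward = back
        return out

    __rmul__ = __mul__

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _make(data, parents) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if p.requires_grad or p._parents)
    out._parents = live
    out.requires_grad = any(p.requires_grad for p in parents)
    return out


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


# ---------------------------------------------------------------------------
# raw conv kernels
# ---------------------------------------------------------------------------

def _pad3(x: np.ndarray, pad: int) -> np.ndarray:
    if not pad:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))


def _tap_slices(k: int, stride: int, out_spatial):
    """For each kernel tap, the strided input slice feeding the output."""
    for tz in range(k):
        for ty in range(k):
            for tx in range(k):
                yield (tz, ty, tx), (
                    slice(None),
                    slice(tz, tz + (out_spatial[0] - 1) * stride + 1, stride),
                    slice(ty, ty + (out_spatial[1] - 1) * stride + 1, stride),
                    slice(tx, tx + (out_spatial[2] - 1) * stride + 1, stride))


def _out_spatial(in_spatial, k, stride, pad):
    return tuple((n + 2 * pad - k) // stride + 1 for n in in_spatial)


def _conv3d_raw(x, W, stride, pad):
    """Convolution as a GEMM per kernel tap over regular strided slices."""
    Cout, Cin, k = W.shape[0], W.shape[1], W.shape[-1]
    xp = _pad3(x, pad)
    out_sp = _out_spatial(x.shape[1:], k, stride, pad)
    L = out_sp[0] * out_sp[1] * out_sp[2]
    y = np.zeros((Cout, L), dtype=np.float32)
    for (tz, ty, tx), sl in _tap_slices(k, stride, out_sp):
        v = np.ascontiguousarray(xp[sl]).reshape(Cin, L)
        y += W[:, :, tz, ty, tx] @ v
    return y.reshape(Cout, *out_sp)


def _conv3d_weight_grad(x, gy, k, stride, pad):
    """Gradient of a conv w.r.t. its weights."""
    Cin = x.shape[0]
    Cout = gy.shape[0]
    xp = _pad3(x, pad)
    out_sp = gy.shape[1:]
    L = out_sp[0] * out_sp[1] * out_sp[2]
    gf = gy.reshape(Cout, L)
    dW = np.empty((Cout, Cin, k, k, k), dtype=np.float32)
    for (tz, ty, tx), sl in _tap_slices(k, stride, out_sp):
        v = np.ascontiguousarray(xp[sl]).reshape(Cin, L)
        dW[:, :, tz, ty, tx] = gf @ v.T
    return dW


def _conv3d_input_grad(gy, W, stride, pad, in_spatial):
    """Gradient of a conv w.r.t. its input; also the transposed-conv forward."""
    Cout, Cin, k = W.shape[0], W.shape[1], W.shape[-1]
    out_sp = gy.shape[1:]
    L = out_sp[0] * out_sp[1] * out_sp[2]
    gf = gy.reshape(Cout, L)
    dXp = np.zeros((Cin, in_spatial[0] + 2 * pad, in_spatial[1] + 2 * pad,
                    in_spatial[2] + 2 * pad), dtype=np.float32)
    for (tz, ty, tx), sl in _tap_slices(k, stride, out_sp):
        dXp[sl] += (W[:, :, tz, ty, tx].T @ gf).reshape(Cin, *out_sp)
    if pad:
        return dXp[:, pad:-pad, pad:-pad, pad:-pad]
    return dXp


def conv3d(x: Tensor, W: Tensor, b: Tensor, stride: int = 1,
           pad: int = 1) -> Tensor:
    """3D convolution; x (Cin, D, H, W), W (Cout, Cin, k, k, k), b (Cout)."""
    y = _conv3d_raw(x.data, W.data, stride, pad)
    y += b.data[:, None, None, None]
    out = _make(y, (x, W, b))
    in_spatial = x.data.shape[1:]
    k = W.data.shape[-1]

    def back(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))
        if W.requires_grad:
            W._accumulate(_conv3d_weight_grad(x.data, g, k, stride, pad))
        if x.requires_grad or x._parents:
            x._accumulate(_conv3d_input_grad(g, W.data, stride, pad,
                                             in_spatial))
    out._backward = back
    return out


def conv_transpose3d(x: Tensor, W: Tensor, b: Tensor, stride: int = 2,
                     pad: int = 1) -> Tensor:
    """Transposed 3D convolution (adjoint of :func:`conv3d`).

    x (Cin, d, h, w); W (Cin, Cout, k, k, k); output spatial size is
    ``(d - 1) * stride - 2 * pad + k`` per axis (exactly doubling for
    k=4, stride=2, pad=1).
    """
    k = W.data.shape[-1]
    d, h, w = x.data.shape[1:]
    out_spatial = tuple((n - 1) * stride - 2 * pad + k for n in (d, h, w))
    y = _conv3d_input_grad(x.data, W.data, stride, pad, out_spatial)
    y += b.data[:, None, None, None]
    out = _make(y, (x, W, b))

    def back(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))
        if W.requires_grad:
            W._accumulate(_conv3d_weight_grad(g, x.data, k, stride, pad))
        if x.requires_grad or x._parents:
            x._accumulate(_conv3d_raw(g, W.data, stride, pad))
    out._backward = back
    return out


def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Fully connected layer on a flat vector."""
    y = W.data @ x.data + b.data
    out = _make(y, (x, W, b))

    def back(g):
        if b.requires_grad:
            b._accumulate(g)
        if W.requires_grad:
            W._accumulate(np.outer(g, x.data))
        if x.requires_grad or x._parents:
            x._accumulate(W.data.T @ g)
    out._backward = back
    return out


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    mask = x.data > 0
    out = _make(np.where(mask, x.data, alpha * x.data), (x,))

    def back(g):
        if x.requires_grad or x._parents:
            x._accumulate(np.where(mask, g, alpha * g))
    out._backward = back
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[0]
    out = _make(np.concatenate([a.data, b.data], axis=0), (a, b))

    def back(g):
        if a.requires_grad or a._parents:
            a._accumulate(g[:na])
        if b.requires_grad or b._parents:
            b._accumulate(g[na:])
    out._backward = back
    return out


def flatten(x: Tensor) -> Tensor:
    shape = x.data.shape
    out = _make(x.data.reshape(-1), (x,))

    def back(g):
        if x.requires_grad or x._parents:
            x._accumulate(g.reshape(shape))
    out._backward = back
    return out


def slice_vector(x: Tensor, start: int, stop: int, shape=None) -> Tensor:
    """Slice a flat vector (used to split the affine head into A and b)."""
    data = x.data[start:stop]
    if shape is not None:
        data = data.reshape(shape)
    out = _make(data, (x,))

    def back(g):
        if x.requires_grad or x._parents:
            full = np.zeros_like(x.data)
            full[start:stop] = g.reshape(-1)
            x._accumulate(full)
    out._backward = back
    return out


# ---------------------------------------------------------------------------
# differentiable trilinear grid sampling
# ---------------------------------------------------------------------------

def _base_grid(shape) -> np.ndarray:
    return np.indices(shape, dtype=np.float32)


def grid_sample(img: Tensor, disp: Tensor) -> Tensor:
    """Warp ``img`` (C, D, H, W) by ``disp`` (3, D, H, W), voxel units.

    ``out(x) = img(x + u(x))`` with trilinear interpolation and zero
    background outside the grid; differentiable in both arguments.
    """
    C = img.data.shape[0]
    shape = img.data.shape[1:]
    phi = (_base_grid(shape) + disp.data).reshape(3, -1)
    f0 = np.floor(phi).astype(np.int64)
    frac = phi - f0
    w_ax = [(1.0 - frac, frac)]  # index by [0][hi][axis]
    strides = (shape[1] * shape[2], shape[2], 1)
    flat = img.data.reshape(C, -1)
    L = phi.shape[1]
    out = np.zeros((C, L), dtype=np.float32)
    corners = []
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                iz, iy, ix = f0[0] + dz, f0[1] + dy, f0[2] + dx
                valid = ((iz >= 0) & (iz < shape[0]) &
                         (iy >= 0) & (iy < shape[1]) &
                         (ix >= 0) & (ix < shape[2]))
                wz = w_ax[0][dz][0]
                wy = w_ax[0][dy][1]
                wx = w_ax[0][dx][2]
                w = np.where(valid, wz * wy * wx, 0.0).astype(np.float32)
                idx = (np.clip(iz, 0, shape[0] - 1) * strides[0] +
                       np.clip(iy, 0, shape[1] - 1) * strides[1] +
                       np.clip(ix, 0, shape[2] - 1))
                vals = flat[:, idx] * valid[None, :]
                out += w[None, :] * vals
                corners.append((dz, dy, dx, valid, idx, wz, wy, wx, vals))
    result = _make(out.reshape(C, *shape), (img, disp))

    def back(g):
        gf = g.reshape(C, -1)
        need_img = img.requires_grad or img._parents
        need_disp = disp.requires_grad or disp._parents
        dimg = np.zeros_like(flat) if need_img else None
        ddisp = np.zeros((3, L), dtype=np.float32) if need_disp else None
        for dz, dy, dx, valid, idx, wz, wy, wx, vals in corners:
            w = np.where(valid, wz * wy * wx, 0.0)
            if need_img:
                contrib = (w[None, :] * gf) * valid[None, :]
                for c in range(C):
                    np.add.at(dimg[c], idx, contrib[c])
            if need_disp:
                gv = (gf * vals).sum(axis=0)  # (L,)
                sz = 1.0 if dz else -1.0
                sy = 1.0 if dy else -1.0
                sx = 1.0 if dx else -1.0
                vm = valid.astype(np.float32)
                ddisp[0] += gv * sz * wy * wx * vm
                ddisp[1] += gv * wz * sy * wx * vm
                ddisp[2] += gv * wz * wy * sx * vm
        if need_img:
            img._accumulate(dimg.reshape(img.data.shape))
        if need_disp:
            disp._accumulate(ddisp.reshape(disp.data.shape))
    result._backward = back
    return result


# ---------------------------------------------------------------------------
# loss operations with analytic gradients
# ---------------------------------------------------------------------------

def cc_loss(fixed: np.ndarray, warped: Tensor) -> Tensor:
    """``1 - CC(fixed, warped)`` with gradient w.r.t. ``warped``."""
    a = np.asarray(fixed, dtype=np.float64).ravel()
    bdat = warped.data.astype(np.float64).ravel()
    ac = a - a.mean()
    bc = bdat - bdat.mean()
    saa = float(ac @ ac)
    sbb = float(bc @ bc)
    if saa == 0.0 or sbb == 0.0:
        warnings.warn("correlation undefined on constant input; loss = 1",
                      stacklevel=2)
        return constant(1.0)
    sab = float(ac @ bc)
    denom = np.sqrt(saa * sbb)
    cc = sab / denom
    out = _make(np.float32(1.0 - cc), (warped,))
    dcc_db = (ac - (sab / sbb) * bc) / denom

    def back(g):
        if warped.requires_grad or warped._parents:
            warped._accumulate(
                (-float(g) * dcc_db).reshape(warped.data.shape))
    out._backward = back
    return out


def orthogonality_loss_t(A: Tensor) -> Tensor:
    """``-6 + sum(mu^2 + mu^-2)`` over singular values of ``I + A``."""
    M = np.eye(3) + A.data.astype(np.float64)
    U, mu, Vt = np.linalg.svd(M)
    if np.any(mu <= 1e-12):
        raise ValueError("I + A is singular; orthogonality loss undefined")
    val = -6.0 + np.sum(mu ** 2 + mu ** -2)
    out = _make(np.float32(val), (A,))
    dmu = 2.0 * mu - 2.0 * mu ** -3
    dM = (U * dmu[None, :]) @ Vt

    def back(g):
        if A.requires_grad or A._parents:
            A._accumulate(float(g) * dM)
    out._backward = back
    return out


def determinant_loss_t(A: Tensor) -> Tensor:
    """``(det(I + A) - 1)^2``."""
    M = np.eye(3) + A.data.astype(np.float64)
    det = np.linalg.det(M)
    out = _make(np.float32((det - 1.0) ** 2), (A,))

    def back(g):
        if A.requires_grad or A._parents:
            dM = 2.0 * (det - 1.0) * det * np.linalg.inv(M).T
            A._accumulate(float(g) * dM)
    out._backward = back
    return out


def affine_field(A: Tensor, b: Tensor, grid_shape) -> Tensor:
    """Dense displacement ``u(x) = A x + b`` as a differentiable op."""
    X = _base_grid(grid_shape)
    u = np.einsum("ij,j...->i...", A.data, X) + b.data[:, None, None, None]
    out = _make(u, (A, b))

    def back(g):
        if A.requires_grad or A._parents:
            A._accumulate(np.einsum("iq,jq->ij", g.reshape(3, -1),
                                    X.reshape(3, -1)))
        if b.requires_grad or b._parents:
            b._accumulate(g.sum(axis=(1, 2, 3)))
    out._backward = back
    return out


def smoothness_loss_t(u: Tensor) -> Tensor:
    """Mean squared forward difference of the field (per-axis mean, /3)."""
    d = u.data.astype(np.float64)
    diffs = []
    total = 0.0
    for ax in range(3):
        sl_lo = [slice(None)] * 4
        sl_hi = [slice(None)] * 4
        sl_lo[ax + 1] = slice(0, -1)
        sl_hi[ax + 1] = slice(1, None)
        dd = d[tuple(sl_hi)] - d[tuple(sl_lo)]
        n = dd[0].size
        total += float(np.sum(dd * dd)) / n
        diffs.append((tuple(sl_lo), tuple(sl_hi), dd, n))
    out = _make(np.float32(total / 3.0), (u,))

    def back(g):
        if u.requires_grad or u._parents:
            grad = np.zeros_like(u.data, dtype=np.float64)
            for sl_lo, sl_hi, dd, n in diffs:
                scale = 2.0 * float(g) / (3.0 * n)
                grad[sl_hi] += scale * dd
                grad[sl_lo] -= scale * dd
            u._accumulate(grad)
    out._backward = back
    return out


def topology_loss_t(u: Tensor) -> Tensor:
    """Mean over interior voxels of ``max(0, -J)`` of ``phi = x + u``."""
    phi = _base_grid(u.data.shape[1:]).astype(np.float64) + \
        u.data.astype(np.float64)
    core = (slice(0, -1),) * 3
    # forward-difference Jacobian entries on the interior grid
    D = np.empty((3, 3) + tuple(s - 1 for s in u.data.shape[1:]))
    shifts = []
    for j in range(3):
        sl = [slice(0, -1)] * 3
        sl[j] = slice(1, None)
        shifts.append(tuple(sl))
    for i in range(3):
        for j in range(3):
            D[i, j] = phi[i][shifts[j]] - phi[i][core]
    J = (D[0, 0] * (D[1, 1] * D[2, 2] - D[1, 2] * D[2, 1])
         - D[0, 1] * (D[1, 0] * D[2, 2] - D[1, 2] * D[2, 0])
         + D[0, 2] * (D[1, 0] * D[2, 1] - D[1, 1] * D[2, 0]))
    N = J.size
    neg = J < 0
    out = _make(np.float32(np.sum(np.where(neg, -J, 0.0)) / N), (u,))

    def back(g):
        if not (u.requires_grad or u._parents):
            return
        gJ = np.where(neg, -float(g) / N, 0.0)
        # cofactors dJ/dD_ij
        C = np.empty_like(D)
        C[0, 0] = D[1, 1] * D[2, 2] - D[1, 2] * D[2, 1]
        C[0, 1] = -(D[1, 0] * D[2, 2] - D[1, 2] * D[2, 0])
        C[0, 2] = D[1, 0] * D[2, 1] - D[1, 1] * D[2, 0]
        C[1, 0] = -(D[0, 1] * D[2, 2] - D[0, 2] * D[2, 1])
        C[1, 1] = D[0, 0] * D[2, 2] - D[0, 2] * D[2, 0]
        C[1, 2] = -(D[0, 0] * D[2, 1] - D[0, 1] * D[2, 0])
        C[2, 0] = D[0, 1] * D[1, 2] - D[0, 2] * D[1, 1]
        C[2, 1] = -(D[0, 0] * D[1, 2] - D[0, 2] * D[1, 0])
        C[2, 2] = D[0, 0] * D[1, 1] - D[0, 1] * D[1, 0]
        grad = np.zeros_like(u.data, dtype=np.float64)
        for i in range(3):
            for j in range(3):
                G = gJ * C[i, j]
                grad[i][shifts[j]] += G
                grad[i][core] -= G
        u._accumulate(grad)
    out._backward = back
    return out


def sum_tensors(ts) -> Tensor:
    ts = list(ts)
    out = ts[0]
    for t in ts[1:]:
        out = out + t
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
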