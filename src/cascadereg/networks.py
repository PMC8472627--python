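"""Coarse affine subnetwork, U-net fine subnetworks, and the n-cascade model.

The model registers a moving volume to a fixed volume in two stages:

* A **coarse subnetwork** sees the channel-concatenated pair, downsamples it
  through stride-2 3x3x3 convolutions to a 4-voxel side, and regresses the
  12 affine parameters (deviation matrix ``A`` and offset ``b``) through a
  fully connected layer.
* ``n`` **fine subnetworks** (recursive cascade modules) each see the
  previously warped image concatenated with the fixed image and predict a
  dense residual displacement field through a 3D U-net (stride-2 encoder,
  transposed-convolution decoder, skip concatenation per matching
  resolution).  The moving image is progressively warped module by module.

Every final prediction layer is zero-initialized, so the untrained model is
exactly the identity transform; all other layers use a seeded fan-in normal
init.  Grids smaller than 128 per side are supported by dropping levels so
the coarsest side is at least 4.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .deform import AffineParams, DisplacementField, affine_to_field, compose
from .volume_io import Volume

_LEAKY_SLOPE = 0.1
_MAX_CHANNELS = 256


def _n_levels(side: int) -> int:
    """Number of stride-2 halvings until the side reaches 4 (>= 1)."""
    if side < 8 or side & (side - 1):
        raise ValueError(f"grid side must be a power of two >= 8, got {side}")
    n = 0
    while side > 4:
        side //= 2
        n += 1
    return n


@dataclass
class CoarseNetConfig:
    input_side: int = 128
    base_channels: int = 16
    conv_kernel: int = 3
    conv_stride: int = 2

    @property
    def level_sides(self) -> list[int]:
        return [self.input_side // 2 ** (i + 1)
                for i in range(_n_levels(self.input_side))]


@dataclass
class FineNetConfig:
    input_side: int = 128
    base_channels: int = 16
    conv_kernel: int = 3
    conv_stride: int = 2
    skip_connections: bool = True

    @property
    def level_sides(self) -> list[int]:
        return [self.input_side // 2 ** (i + 1)
                for i in range(_n_levels(self.input_side))]


def _conv_params(rng, cout, cin, k, zero=False):
    if zero:
        w = np.zeros((cout, cin, k, k, k), dtype=np.float32)
    else:
        fan_in = cin * k ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (cout, cin, k, k, k)).astype(np.float32)
    return Parameter(w), Parameter(np.zeros(cout, dtype=np.float32))


class CoarseNet:
    """Affine-parameter regressor; zero-initialized head => identity."""

    def __init__(self, config: CoarseNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.convs = []
        cin = 2
        side = config.input_side
        for i in range(_n_levels(config.input_side)):
            cout = min(config.base_channels * 2 ** i, _MAX_CHANNELS)
            self.convs.append(_conv_params(rng, cout, cin, config.conv_kernel))
            cin = cout
            side //= 2
        feat = cin * side ** 3
        self.fc_W = Parameter(np.zeros((12, feat), dtype=np.float32))
        self.fc_b = Parameter(np.zeros(12, dtype=np.float32))

    def parameters(self) -> list[Parameter]:
        ps = []
        for w, b in self.convs:
            ps += [w, b]
        ps += [self.fc_W, self.fc_b]
        return ps

    def forward(self, moving: Tensor, fixed: Tensor
                ) -> tuple[Tensor, Tensor]:
        """Return the affine deviation ``A`` (3, 3) and offset ``b`` (3,)."""
        if moving.shape[-1] != self.config.input_side:
            raise ValueError(
                f"input side {moving.shape[-1]} does not match configured "
                f"side {self.config.input_side}")
        h = ad.concat_channels(moving, fixed)
        for w, b in self.convs:
            h = ad.leaky_relu(ad.conv3d(h, w, b, stride=2, pad=1),
                              _LEAKY_SLOPE)
        out = ad.linear(ad.flatten(h), self.fc_W, self.fc_b)
        A = ad.slice_vector(out, 0, 9, shape=(3, 3))
        b_vec = ad.slice_vector(out, 9, 12)
        return A, b_vec


class FineNet:
    """3D U-net emitting a residual displacement field at input resolution."""

    def __init__(self, config: FineNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        L = _n_levels(config.input_side)
        bc = config.base_channels
        ch = [min(bc * 2 ** i, _MAX_CHANNELS) for i in range(L + 1)]
        k = config.conv_kernel
        self.stem = _conv_params(rng, ch[0], 2, k)
        self.enc = [_conv_params(rng, ch[i + 1], ch[i], k) for i in range(L)]
        # decoder: transposed conv (k=4, s=2) then a fusing conv after skip
        self.up = []
        self.dec = []
        for i in reversed(range(L)):
            cin = ch[i + 1]
            cout = ch[i]
            wu = rng.normal(0.0, np.sqrt(2.0 / (cin * 64)),
                            (cin, cout, 4, 4, 4)).astype(np.float32)
            self.up.append((Parameter(wu),
                            Parameter(np.zeros(cout, dtype=np.float32))))
            skip = ch[i] if config.skip_connections else 0
            self.dec.append(_conv_params(rng, cout, cout + skip, k))
        self.head = _conv_params(rng, 3, ch[0], k, zero=True)

    def parameters(self) -> list[Parameter]:
        ps = list(self.stem)
        for pair in self.enc + self.up + self.dec:
            ps += list(pair)
        ps += list(self.head)
        return ps

    def forward(self, warped_prev: Tensor, fixed: Tensor) -> Tensor:
        """Predict a (3, D, H, W) displacement field, voxel units."""
        h = ad.concat_channels(warped_prev, fixed)
        h = ad.leaky_relu(ad.conv3d(h, *self.stem, stride=1, pad=1),
                          _LEAKY_SLOPE)
        skips = [h]
        for w, b in self.enc:
            h = ad.leaky_relu(ad.conv3d(h, w, b, stride=2, pad=1),
                              _LEAKY_SLOPE)
            skips.append(h)
        skips.pop()  # bottom level is h itself
        for (wu, bu), (wd, bd) in zip(self.up, self.dec):
            h = ad.leaky_relu(ad.conv_transpose3d(h, wu, bu, stride=2, pad=1),
                              _LEAKY_SLOPE)
            if self.config.skip_connections:
                h = ad.concat_channels(h, skips.pop())
            h = ad.leaky_relu(ad.conv3d(h, wd, bd, stride=1, pad=1),
                              _LEAKY_SLOPE)
        return ad.conv3d(h, *self.head, stride=1, pad=1)


@dataclass
class CascadeConfig:
    """Architecture of the full coarse-to-fine cascade."""

    grid_side: int = 128
    n_cascades: int = 7
    base_channels: int = 16
    seed: int = 0


class CascadeModel:
    """One coarse subnetwork followed by ``n`` recursive cascade modules."""

    def __init__(self, config: CascadeConfig):
        if config.n_cascades < 0:
            raise ValueError("n_cascades must be >= 0")
        self.config = config
        self.coarse = CoarseNet(
            CoarseNetConfig(config.grid_side, config.base_channels),
            seed=config.seed)
        # independent parameters per cascade (no weight sharing)
        self.fines = [
            FineNet(FineNetConfig(config.grid_side, config.base_channels),
                    seed=config.seed + 1 + k)
            for k in range(config.n_cascades)]

    @property
    def n(self) -> int:
        return len(self.fines)

    def parameters(self, include_coarse: bool = True) -> list[Parameter]:
        ps = self.coarse.parameters() if include_coarse else []
        for f in self.fines:
            ps += f.parameters()
        return ps

    def coarse_forward(self, moving: Volume, fixed: Volume) -> AffineParams:
        """Affine prediction only, as plain parameters."""
        A, b = self.coarse.forward(ad.constant(moving.data[None]),
                                   ad.constant(fixed.data[None]))
        return AffineParams(A.data.astype(np.float64),
                            b.data.astype(np.float64))

    def fine_forward(self, k: int, warped_prev: Volume,
                     fixed: Volume) -> DisplacementField:
        """Displacement prediction of the k-th cascade (1-based)."""
        if not 1 <= k <= self.n:
            raise IndexError(f"cascade index {k} outside 1..{self.n}")
        f = self.fines[k - 1].forward(ad.constant(warped_prev.data[None]),
                                      ad.constant(fixed.data[None]))
        return DisplacementField(f.data)

    def forward_tensors(self, moving: Volume, fixed: Volume):
        """Differentiable forward pass.

        Returns ``(warped_stages, A, b, field_tensors)`` where
        ``warped_stages[0]`` is the affine-warped image tensor and
        ``warped_stages[-1]`` the final warped image tensor.
        """
        if moving.shape != (self.config.grid_side,) * 3:
            raise ValueError(
                f"inputs must be {self.config.grid_side}^3, got {moving.shape}")
        mov_t = ad.constant(moving.data[None])
        fix_t = ad.constant(fixed.data[None])
        A, b = self.coarse.forward(mov_t, fix_t)
        aff_u = ad.affine_field(A, b, moving.shape)
        warped = ad.grid_sample(mov_t, aff_u)
        stages = [warped]
        fields = []
        for fine in self.fines:
            u = fine.forward(warped, fix_t)
            warped = ad.grid_sample(warped, u)
            stages.append(warped)
            fields.append(u)
        return stages, A, b, fields

    def predict(self, moving: Volume, fixed: Volume):
        """Inference pass.

        Returns ``(final_warped, affine, fields, composite)`` where
        ``composite`` is the single field equivalent (up to interpolation)
        to the progressive warps, built with :func:`cascadereg.deform.compose`.
        """
        stages, A, b, fields = self.forward_tensors(moving, fixed)
        affine = AffineParams(A.data.astype(np.float64),
                              b.data.astype(np.float64))
        field_objs = [DisplacementField(f.data) for f in fields]
        composite = affine_to_field(affine, moving.shape)
        for f in field_objs:
            composite = compose(composite, f)
        final = Volume(stages[-1].data[0], moving.spacing_mm, moving.origin)
        return final, affine, field_objs, composite


def save_checkpoint(model: CascadeModel, path) -> None:
    """Serialize parameters with the architecture config embedded."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, config=np.str_(json.dumps(asdict(model.config))), **arrays)


def load_checkpoint(path) -> CascadeModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path, allow_pickle=False) as z:
        cfg = CascadeConfig(**json.loads(str(z["config"])))
        model = CascadeModel(cfg)
        params = model.parameters()
        for i, p in enumerate(params):
            stored = z[f"p{i}"]
            if stored.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint parameter {i} has shape {stored.shape}, "
                    f"expected {p.data.shape}")
            p.data = stored.astype(np.float32)
    return model
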