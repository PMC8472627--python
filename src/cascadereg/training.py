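"""Unsupervised end-to-end training of the cascade.

The central object is :class:`CascadeRegistrator`, a scikit-learn style
estimator: construct with hyperparameters, ``fit`` on a
:class:`PairDataset` (or a plain list of cases), then ``register`` /
``transform`` held-out pairs.  The module-level ``train`` / ``register`` /
``ablate_cascades`` functions are thin wrappers over it.

Training minimizes the total loss (coarse similarity + affine regularizers
+ fine similarity + per-cascade smoothness and folding penalties) with Adam.
Defaults: batch size 2, 5 epochs, learning rate 1e-4, l1 = l2 = 1e-1,
l3 = l4 = 1e-5.  Everything is seeded and CPU-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .deform import DisplacementField, warp
from .evaluation import evaluate_case
from .losses import LossReport, LossWeights
from .networks import CascadeConfig, CascadeModel
from .phantom import RegistrationCase, make_atlas_cohort
from .volume_io import LabelVolume, Volume


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the training protocol."""

    batch_size: int = 2
    epochs: int = 5
    learning_rate: float = 1e-4
    weights: LossWeights = dc_field(default_factory=LossWeights)
    n_cascades: int = 7
    grid_side: int = 128
    base_channels: int = 16
    seed: int = 0
    freeze_coarse: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate < 0:
            raise ValueError("batch_size, epochs, learning_rate must be valid")


def desk_scale_config(**overrides) -> TrainConfig:
    """The shipped desk-scale profile: 32-cube grids, 8 base channels."""
    cfg = TrainConfig(grid_side=32, base_channels=8, n_cascades=2)
    return replace(cfg, **overrides)


@dataclass
class PairDataset:
    """All-pairs-to-atlas dataset: every case shares the fixed image."""

    atlas: tuple[Volume, LabelVolume]
    movers: list  # (Volume, LabelVolume, AffineParams, DisplacementField)
    train_idx: list[int]
    test_idx: list[int]

    def __len__(self) -> int:
        return len(self.movers)

    def case(self, i: int) -> RegistrationCase:
        mv, ml, aff, field = self.movers[i]
        return RegistrationCase(fixed=self.atlas[0], moving=mv,
                                fixed_labels=self.atlas[1], moving_labels=ml,
                                affine_gt=aff, field_gt=field)

    def train_cases(self):
        return [self.case(i) for i in self.train_idx]

    def test_cases(self):
        return [self.case(i) for i in self.test_idx]


def make_phantom_dataset(n_pairs: int, phantom_spec, deform_spec,
                         test_fraction: float = 0.25) -> PairDataset:
    """Simulate an atlas cohort and split it into train/test pairs."""
    atlas, movers = make_atlas_cohort(n_pairs, phantom_spec, deform_spec)
    if test_fraction <= 0 or n_pairs < 2:
        n_test = 0
    else:
        n_test = min(n_pairs - 1, max(1, int(round(n_pairs * test_fraction))))
    idx = list(range(n_pairs))
    return PairDataset(atlas=atlas, movers=movers,
                       train_idx=idx[:n_pairs - n_test],
                       test_idx=idx[n_pairs - n_test:])


class NonFiniteLossError(RuntimeError):
    """Raised when a loss term stops being finite during training."""


class CascadeRegistrator(BaseEstimator):
    """Coarse-to-fine recursive-cascade registration estimator.

    Parameters
    ----------
    n_cascades : int
        Number of recursive fine modules (0 = affine-only model).
    grid_side : int
        Cubic grid side; inputs must be preprocessed to this size.
    base_channels : int
        Channels of the first convolution; doubled per level, capped at 256.
    batch_size, epochs, learning_rate : optimization settings.
    lambda1, lambda2 : affine orthogonality / determinant weights.
    lambda3, lambda4 : per-cascade smoothness / folding-penalty weights.
    seed : int
        Seeds parameter init and the per-epoch pair shuffling.
    freeze_coarse : bool
        If True the coarse subnetwork is excluded from the optimizer.

    Attributes
    ----------
    model_ : CascadeModel
        The fitted network.
    history_ : pandas.DataFrame
        Per-step loss decomposition (``total = coarse + fine`` exactly).
    """

    def __init__(self, n_cascades: int = 2, grid_side: int = 32,
                 base_channels: int = 8, batch_size: int = 2,
                 epochs: int = 5, learning_rate: float = 1e-4,
                 lambda1: float = 1e-1, lambda2: float = 1e-1,
                 lambda3: float = 1e-5, lambda4: float = 1e-5,
                 seed: int = 0, freeze_coarse: bool = False):
        self.n_cascades = n_cascades
        self.grid_side = grid_side
        self.base_channels = base_channels
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.lambda4 = lambda4
        self.seed = seed
        self.freeze_coarse = freeze_coarse

    # -- internals ----------------------------------------------------------

    def _weights(self) -> LossWeights:
        return LossWeights(self.lambda1, self.lambda2,
                           self.lambda3, self.lambda4)

    def _build(self) -> CascadeModel:
        return CascadeModel(CascadeConfig(
            grid_side=self.grid_side, n_cascades=self.n_cascades,
            base_channels=self.base_channels, seed=self.seed))

    def _case_loss(self, model: CascadeModel, case: RegistrationCase):
        """Differentiable total loss of one pair; returns (tensor, report)."""
        w = self._weights()
        stages, A, b, fields = model.forward_tensors(case.moving, case.fixed)
        fixed = case.fixed.data
        sim_c = ad.cc_loss(fixed, stages[0])
        lr1 = ad.orthogonality_loss_t(A)
        lr2 = ad.determinant_loss_t(A)
        coarse = sim_c + w.lambda1 * lr1 + w.lambda2 * lr2
        rep = LossReport(sim_coarse=sim_c.item(), ortho=lr1.item(),
                         det=lr2.item(), coarse_total=coarse.item())
        total = coarse
        if fields:
            sim_f = ad.cc_loss(fixed, stages[-1])
            lr3 = ad.sum_tensors([ad.smoothness_loss_t(f) for f in fields])
            lr4 = ad.sum_tensors([ad.topology_loss_t(f) for f in fields])
            fine = sim_f + w.lambda3 * lr3 + w.lambda4 * lr4
            rep.sim_fine = sim_f.item()
            rep.smooth = lr3.item()
            rep.topo = lr4.item()
            rep.fine_total = fine.item()
            total = coarse + fine
        rep.total = total.item()
        for name in ("total", "coarse_total", "fine_total", "sim_coarse",
                     "sim_fine", "ortho", "det", "smooth", "topo"):
            if not np.isfinite(getattr(rep, name)):
                raise NonFiniteLossError(
                    f"loss term {name!r} became non-finite during training")
        return total, rep

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None, checkpoint_dir=None) -> "CascadeRegistrator":
        """Train on a :class:`PairDataset` or a sequence of cases.

        When ``checkpoint_dir`` is given, the model is checkpointed after
        every epoch (``epoch_<e>.npz``, architecture config embedded).
        """
        cases = X.train_cases() if isinstance(X, PairDataset) else list(X)
        if not cases:
            raise ValueError("training set is empty")
        for c in cases:
            if c.fixed.shape != (self.grid_side,) * 3:
                raise ValueError(
                    f"case grid {c.fixed.shape} does not match grid_side "
                    f"{self.grid_side}")
        model = self._build()
        params = model.parameters(include_coarse=not self.freeze_coarse)
        opt = ad.Adam(params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        rows = []
        step = 0
        for epoch in range(self.epochs):
            order = rng.permutation(len(cases))
            for start in range(0, len(order), self.batch_size):
                batch = [cases[i] for i in order[start:start + self.batch_size]]
                opt.zero_grad()
                reports = []
                for case in batch:
                    total, rep = self._case_loss(model, case)
                    # mean loss over the batch
                    (total * (1.0 / len(batch))).backward()
                    reports.append(rep)
                if self.learning_rate > 0:
                    opt.step()
                row = {"step": step, "epoch": epoch}
                mean = LossReport(*[float(np.mean([getattr(r, f) for r in reports]))
                                    for f in ("total", "coarse_total",
                                              "fine_total", "sim_coarse",
                                              "sim_fine", "ortho", "det",
                                              "smooth", "topo")])
                row.update(mean.row(step))
                rows.append(row)
                step += 1
            if checkpoint_dir is not None:
                from pathlib import Path
                from .networks import save_checkpoint
                ckdir = Path(checkpoint_dir)
                ckdir.mkdir(parents=True, exist_ok=True)
                save_checkpoint(model, ckdir / f"epoch_{epoch}.npz")
        self.model_ = model
        self.history_ = pd.DataFrame(rows)
        return self

    def register(self, moving: Volume, fixed: Volume,
                 moving_labels: LabelVolume | None = None):
        """Register one pair.

        Returns ``(warped, composite_field)`` or, when ``moving_labels`` is
        given, ``(warped, composite_field, warped_labels)`` with the labels
        warped nearest-neighbour by the same field.
        """
        if not hasattr(self, "model_"):
            self.model_ = self._build()  # identity-initialized
        final, affine, fields, composite = self.model_.predict(moving, fixed)
        if moving_labels is not None:
            warped_labels = warp(moving_labels, composite, mode="nearest")
            return final, composite, warped_labels
        return final, composite

    def transform(self, X):
        """Register every case; returns a list of (warped, field) tuples."""
        cases = X.test_cases() if isinstance(X, PairDataset) else list(X)
        return [self.register(c.moving, c.fixed) for c in cases]

    def predict(self, X):
        return self.transform(X)

    def score_cases(self, cases) -> pd.DataFrame:
        """Nine-metric evaluation of each registered case."""
        rows = []
        for c in cases:
            warped, field, warped_labels = self.register(
                c.moving, c.fixed, c.moving_labels)
            rows.append(evaluate_case(c.fixed, warped, c.fixed_labels,
                                      warped_labels).as_dict())
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train(model_or_cfg, dataset: PairDataset, cfg: TrainConfig | None = None):
    """Train a cascade on a dataset; returns (estimator, history)."""
    cfg = cfg or (model_or_cfg if isinstance(model_or_cfg, TrainConfig)
                  else TrainConfig())
    est = CascadeRegistrator(
        n_cascades=cfg.n_cascades, grid_side=cfg.grid_side,
        base_channels=cfg.base_channels, batch_size=cfg.batch_size,
        epochs=cfg.epochs, learning_rate=cfg.learning_rate,
        lambda1=cfg.weights.lambda1, lambda2=cfg.weights.lambda2,
        lambda3=cfg.weights.lambda3, lambda4=cfg.weights.lambda4,
        seed=cfg.seed, freeze_coarse=cfg.freeze_coarse)
    est.fit(dataset)
    return est, est.history_


def register(est: CascadeRegistrator, moving: Volume, fixed: Volume,
             moving_labels: LabelVolume | None = None):
    """Single forward registration pass (see estimator method)."""
    return est.register(moving, fixed, moving_labels)


def ablate_cascades(dataset: PairDataset, cfg: TrainConfig,
                    n_values: list[int]) -> pd.DataFrame:
    """Train one model per cascade count and evaluate the test split.

    All runs share seeds and data; returns one row per ``n`` with the mean
    of each of the nine metrics over the test cases.
    """
    if not n_values:
        raise ValueError("n_values must be nonempty")
    rows = []
    for n in n_values:
        run_cfg = replace(cfg, n_cascades=n)
        est, _ = train(run_cfg, dataset)
        scores = est.score_cases(dataset.test_cases())
        row = {"n_cascades": n}
        row.update(scores.mean(numeric_only=True).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
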