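"""Desk-scale study protocols: reproducible end-to-end experiments.

Each function simulates its own phantom cohort from a single integer seed,
trains the cascade under a fixed protocol and measures the quantity of
interest.  Problem sizes are chosen so each experiment runs in minutes on
one CPU (see the methods note); all randomness derives from the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deform import jacobian_determinant
from .phantom import DeformationSpec, PhantomSpec
from .training import CascadeRegistrator, TrainConfig, ablate_cascades, \
    make_phantom_dataset

GRID_SIDE = 32
BASE_CHANNELS = 8


def _phantom_spec(seed: int) -> PhantomSpec:
    return PhantomSpec(grid_shape=(GRID_SIDE,) * 3, seed=seed)


def loss_decrease_experiment(seed: int = 0) -> dict:
    """Train the 2-cascade model for 5 epochs on 10 phantom pairs and
    compare the first- and final-epoch mean total loss.

    Protocol: batch size 2, learning rate 1e-4, default loss weights.
    """
    ds = make_phantom_dataset(10, _phantom_spec(seed + 7),
                              DeformationSpec(seed=seed + 100),
                              test_fraction=0.0)
    est = CascadeRegistrator(n_cascades=2, grid_side=GRID_SIDE,
                             base_channels=BASE_CHANNELS, batch_size=2,
                             epochs=5, learning_rate=1e-4, seed=seed)
    est.fit(ds)
    h = est.history_
    return {
        "first_epoch_mean_total": float(h[h.epoch == 0].total.mean()),
        "final_epoch_mean_total": float(h[h.epoch == h.epoch.max()]
                                        .total.mean()),
        "n_pairs": len(ds),
        "history": h,
    }


def translation_recovery_experiment(seed: int = 0) -> dict:
    """Train the coarse subnetwork on pure-translation pairs and measure
    how well it recovers the translation on held-out pairs.

    The ground-truth map is ``x -> x + t``; a perfect registration applies
    the inverse, so the recovered offset is compared against ``-t``.  The
    network is free to split a translation between its linear term ``A x``
    and its offset ``b``, so the comparable quantity is the effective
    translation at the grid centre, ``A c + b``.

    Protocol: 44 pairs (40 train / 4 held out), translations up to 3
    voxels, 150 epochs at learning rate 1e-3.
    """
    dspec = DeformationSpec(affine_scale_range=(1.0, 1.0),
                            affine_rotation_max_deg=0.0,
                            affine_translation_max_vox=3.0,
                            nonrigid_amplitude_vox=0.0, seed=seed + 500)
    ds = make_phantom_dataset(44, _phantom_spec(seed + 11), dspec,
                              test_fraction=0.1)
    est = CascadeRegistrator(n_cascades=0, grid_side=GRID_SIDE,
                             base_channels=BASE_CHANNELS, epochs=150,
                             learning_rate=1e-3, seed=seed + 1)
    est.fit(ds)
    centre = (np.array([GRID_SIDE] * 3) - 1) / 2.0
    errors = []
    for case in ds.test_cases():
        pred = est.model_.coarse_forward(case.moving, case.fixed)
        t_recovered = pred.A @ centre + pred.b
        errors.append(float(np.linalg.norm(t_recovered + case.affine_gt.b)))
    return {"mean_error_vox": float(np.mean(errors)),
            "errors_vox": errors, "n_heldout": len(errors),
            "estimator": est}


def cascade_ablation_experiment(seed: int = 0,
                                n_values=(0, 1, 3)) -> pd.DataFrame:
    """Train one model per cascade count on a shared cohort and evaluate
    the nine metrics on the shared test split.

    Protocol: 10 pairs (8 train / 2 test), 20 epochs at learning rate 1e-3.
    """
    ds = make_phantom_dataset(10, _phantom_spec(seed + 7),
                              DeformationSpec(seed=seed + 100),
                              test_fraction=0.2)
    cfg = TrainConfig(grid_side=GRID_SIDE, base_channels=BASE_CHANNELS,
                      epochs=20, learning_rate=1e-3, seed=seed)
    return ablate_cascades(ds, cfg, list(n_values))


def topology_experiment(seed: int = 0) -> dict:
    """Measure folding (fraction of interior voxels with negative Jacobian
    determinant of the composite field) on test pairs, for the model
    trained with the default folding penalty and for a paired run with the
    penalty removed.

    Protocol: 10 pairs (8 train / 2 test), 2 cascades, 20 epochs at
    learning rate 1e-3; both runs share seeds and data.
    """
    ds = make_phantom_dataset(10, _phantom_spec(seed + 7),
                              DeformationSpec(seed=seed + 100),
                              test_fraction=0.2)

    def negative_fraction(lambda4: float) -> float:
        est = CascadeRegistrator(n_cascades=2, grid_side=GRID_SIDE,
                                 base_channels=BASE_CHANNELS, epochs=20,
                                 learning_rate=1e-3, seed=seed,
                                 lambda4=lambda4)
        est.fit(ds)
        fractions = []
        for case in ds.test_cases():
            _, field = est.register(case.moving, case.fixed)
            J = jacobian_determinant(field)[:-1, :-1, :-1]
            fractions.append(float((J < 0).mean()))
        return float(np.mean(fractions))

    return {"negative_fraction_default": negative_fraction(1e-5),
            "negative_fraction_no_penalty": negative_fraction(0.0)}
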