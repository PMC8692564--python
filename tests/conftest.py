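"""Shared fixtures: small planted datasets and one expensive recovery run.

The parameter-recovery study (5 subjects, T=100, V=500, 5 planted
networks, SNR 5, lambda 0.2) is trained once per seed at session scope
and reused by both the unit-level recovery checks and the acceptance
suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from nasdbn.dbn import Architecture, spatial_maps, temporal_features, train_greedy
from nasdbn.rbm import TrainConfig
from nasdbn.synthetic import make_dataset

# training settings used for the desk-scale recovery studies: stronger
# learning rate / fewer units than the full-scale configuration, sized to
# the small planted problems
RECOVERY_TRAIN = dict(
    learning_rate=0.05, batch_size=10, epochs=60,
    sparsity_target=0.05, sparsity_weight=10.0,
)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two binary supports."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    return float(2 * (a & b).sum() / s) if s else 0.0


def matched_abs_corr(features: np.ndarray, truth_tc: np.ndarray) -> np.ndarray:
    """Hungarian-matched |Pearson r| between feature columns and planted
    time courses; returns one value per planted course."""
    t = features.shape[0]
    fz = features - features.mean(axis=0)
    fsd = fz.std(axis=0)
    fz = fz / np.where(fsd > 0, fsd, 1.0)
    gz = (truth_tc - truth_tc.mean(axis=0)) / truth_tc.std(axis=0)
    corr = np.abs(fz.T @ gz) / t          # atoms x K
    row, col = linear_sum_assignment(-corr)
    out = np.zeros(truth_tc.shape[1])
    out[col] = corr[row, col]
    return out


def run_recovery(seed: int):
    """One study-scale recovery run: train a 2-layer DBN on planted
    data and score temporal + spatial recovery of the 5 planted networks."""
    subjects, truth = make_dataset(
        n_subjects=5, t_per_subject=100, n_voxels=500,
        k_primary=5, k_composite=0, lambda_primary=0.2, lambda_composite=0.6,
        snr=5.0, seed=seed,
    )
    x = np.vstack([s.values.T for s in subjects])
    cfg = TrainConfig(seed=seed, **RECOVERY_TRAIN)
    weights = train_greedy(x, Architecture(2, 8, validate=False), cfg)

    corr = matched_abs_corr(temporal_features(weights, 1), truth.group_timecourses)
    maps = spatial_maps(weights, subjects[0], 1)
    best_dice = np.array([
        max(dice(maps.supports[a], truth.maps[k]) for a in range(maps.n_atoms))
        for k in range(truth.n_networks)
    ])
    return {"corr": corr, "dice": best_dice, "weights": weights,
            "subjects": subjects, "truth": truth}


@pytest.fixture(scope="session")
def recovery_results():
    return {seed: run_recovery(seed) for seed in (1, 2, 3)}


@pytest.fixture()
def tiny_dataset():
    subjects, truth = make_dataset(
        n_subjects=3, t_per_subject=60, n_voxels=200, k_primary=3,
        k_composite=1, seed=7,
    )
    return subjects, truth
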