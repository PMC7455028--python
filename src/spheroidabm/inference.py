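"""Inferring spheroid composition and cell-line parameters from beads.

Each simulated infiltration experiment is summarised by the feature pair
(T_wait, V_r) — the mean bead waiting time and mean inward radial
velocity. A sweep over randomly drawn (tau, omega_q) produces a labelled
dataset; a k-nearest-neighbour regressor (k = 10, unweighted mean over
neighbours in standardised feature space) then predicts compartment
proportions and the generating parameters for held-out runs, scored by
the coefficient of determination R^2.

Features are z-scored on training statistics before distance computation
because the two features have incompatible natural scales (hours versus
cell diameters per hour); pass ``standardise=False`` to disable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.neighbors import KNeighborsRegressor

from . import analysis
from .state import SimulationConfig, make_config

__all__ = [
    "SweepRecord",
    "run_sweep",
    "split",
    "knn_predict",
    "r_squared",
    "FEATURES",
    "TARGETS",
]

FEATURES = ("T_wait", "V_r")
TARGETS = ("prop_quiescent", "prop_prolif", "prop_hypoxic", "prop_necrotic", "tau", "omega_q")


@dataclass
class SweepRecord:
    """Summary of one completed infiltration run in a parameter sweep."""

    run_id: int
    tau: float
    omega_q: float
    T_wait: float
    V_r: float
    prop_prolif: float
    prop_quiescent: float
    prop_hypoxic: float
    prop_necrotic: float
    seed: int


def summarise_run(result, run_id: int = 0, seed: int = 0, tau: float = 0.0,
                  omega_q: float = 0.0, window: float = 5.0,
                  end_fallback: Optional[bool] = None) -> Optional[SweepRecord]:
    """Reduce one infiltration result to a sweep record.

    Computes D_est from the first ``window`` hours of bead motion, the
    regime-threshold series, per-bead summaries, their population means,
    and the compartment proportions of the snapshot at bead addition.
    ``end_fallback=None`` (default) substitutes the trajectory end for
    core arrival only when the spheroid never forms a necrotic core;
    True forces the fallback for every bead (used in short scaled-down
    tracking windows where few beads reach the core in time). Returns
    None when no bead yields both statistics.
    """
    D_est = analysis.estimate_D(result.trajectories, window=window)
    thresholds = analysis.regime_threshold(
        result.spheroid_radius, result.times, D_est
    )
    if end_fallback is None:
        end_fallback = not bool(np.any(result.necrotic_radius > 0))
    summaries = [
        analysis.summarise_bead(
            traj, thresholds, result.necrotic_radius, allow_end_fallback=end_fallback
        )
        for traj in result.trajectories
    ]
    try:
        means = analysis.population_means(summaries)
    except ValueError:
        return None
    # composition at the moment beads were added (end of the growth phase)
    t_add = result.snapshots[-1].time - result.times[-1]
    snap = min(result.snapshots, key=lambda s: abs(s.time - t_add))
    comp = analysis.composition_summary(snap)
    props = comp.proportions
    from .state import Phenotype

    return SweepRecord(
        run_id=run_id,
        tau=tau,
        omega_q=omega_q,
        T_wait=means.T_wait,
        V_r=means.V_r,
        prop_prolif=props[int(Phenotype.PROLIFERATIVE)],
        prop_quiescent=props[int(Phenotype.QUIESCENT)],
        prop_hypoxic=props[int(Phenotype.HYPOXIC)],
        prop_necrotic=props[int(Phenotype.NECROTIC)],
        seed=seed,
    )


def run_sweep(
    n_runs: int,
    tau_range: Tuple[float, float],
    omega_q_range: Tuple[float, float],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    end_fallback: Optional[bool] = None,
) -> List[SweepRecord]:
    """Run ``n_runs`` infiltration experiments with random (tau, omega_q).

    Parameters are drawn uniformly from the given ranges (omega_q must
    stay above the fixed omega_h in ``cfg``); each run gets its own seed
    derived from ``rng``. Failed runs are skipped and reported.
    """
    from .engine import run_infiltration

    if omega_q_range[0] <= cfg.omega_h:
        raise ValueError("omega_q range must lie strictly above the fixed omega_h")
    records: List[SweepRecord] = []
    n_failed = 0
    for i in range(n_runs):
        tau = float(rng.uniform(*tau_range))
        omega_q = float(rng.uniform(*omega_q_range))
        seed = int(rng.integers(0, 2**31 - 1))
        run_cfg = make_config(cfg.to_dict() | {"tau": tau, "omega_q": omega_q, "seed": seed})
        try:
            result = run_infiltration(run_cfg)
            rec = summarise_run(result, run_id=i, seed=seed, tau=tau, omega_q=omega_q,
                                end_fallback=end_fallback)
        except (RuntimeError, ValueError):
            rec = None
        if rec is None:
            n_failed += 1
            continue
        records.append(rec)
    if n_failed:
        import logging

        logging.getLogger(__name__).warning(
            "sweep: %d of %d runs failed or yielded no bead statistics", n_failed, n_runs
        )
    return records


def split(
    records: Sequence, n_train: int, rng: np.random.Generator
) -> Tuple[list, list]:
    """Random disjoint, exhaustive train/test partition."""
    n = len(records)
    if n_train >= n:
        raise ValueError(f"n_train={n_train} must be smaller than the dataset ({n})")
    perm = rng.permutation(n)
    train = [records[i] for i in perm[:n_train]]
    test = [records[i] for i in perm[n_train:]]
    return train, test


def _feature_matrix(records: Sequence) -> np.ndarray:
    return np.array([[getattr(r, f) for f in FEATURES] for r in records], dtype=float)


def knn_predict(
    train: Sequence,
    test: Sequence,
    target: str,
    k: int = 10,
    standardise: bool = True,
) -> np.ndarray:
    """k-nearest-neighbour regression of ``target`` from (T_wait, V_r).

    Prediction is the unweighted mean of the target over the k nearest
    training records in (optionally z-scored) Euclidean feature space;
    neighbour ties at equal distance break by training-record order.
    """
    if k > len(train):
        raise ValueError(f"k={k} exceeds the training-set size {len(train)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    X_train = _feature_matrix(train)
    X_test = _feature_matrix(test)
    y_train = np.array([getattr(r, target) for r in train], dtype=float)
    if standardise:
        mean = X_train.mean(axis=0)
        std = X_train.std(axis=0)
        std[std == 0] = 1.0
        X_train = (X_train - mean) / std
        X_test = (X_test - mean) / std
    model = KNeighborsRegressor(n_neighbors=k, weights="uniform", algorithm="brute")
    model.fit(X_train, y_train)
    return model.predict(X_test)


def r_squared(truth: Sequence[float], predictions: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(truth, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if y.shape != p.shape or y.size < 2:
        raise ValueError("truth and predictions must be equal-length with >= 2 entries")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant truth")
    ss_res = float(((y - p) ** 2).sum())
    return 1.0 - ss_res / ss_tot
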