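"""Diversity-driven training-set reduction gated by validation RMSE.

Starting from a random seed set, candidates are proposed one at a time —
either by largest minimum Euclidean distance to the selected set (``ebd``)
or uniformly at random (``rs``) — and a candidate is kept only when the
validation RMSE of the retrained model strictly decreases.  Every pool
sample is evaluated exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import DimensionError, PoolExhausted, ValidationError
from .regression import GPRModel, predict, r2, rmse, train_gpr


@dataclass
class ALState:
    """Outcome of one accept/reject pass over the candidate pool."""

    selected_indices: list[int]
    rmse_trace: list[float]          # validation RMSE after each accepted sample
    r2_trace: list[float]
    evaluated_count: int
    seed: int
    eval_log: list[dict] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        """Per-evaluation log (step, pool_index, accepted, rmse, r2)."""
        return pd.DataFrame(self.eval_log,
                            columns=["step", "pool_index", "accepted",
                                     "rmse", "r2"])

    def save_trace(self, path: str | Path) -> None:
        self.trace_frame().to_csv(path, index=False)


def ebd_next(pool_features: np.ndarray, selected_features: np.ndarray) -> int:
    """Index of the pool row with the largest minimum distance to the
    selected set; ties broken by lowest index."""
    pool = np.atleast_2d(np.asarray(pool_features, dtype=float))
    sel = np.atleast_2d(np.asarray(selected_features, dtype=float))
    if pool.shape[0] == 0:
        raise PoolExhausted("candidate pool is empty")
    if sel.shape[0] == 0:
        raise ValidationError("selected set must be non-empty")
    if pool.shape[1] != sel.shape[1]:
        raise DimensionError("pool and selected feature dimensions differ")
    min_dist = cdist(pool, sel).min(axis=1)
    return int(np.argmax(min_dist))  # argmax returns the first (lowest) index


def _evaluate(model: GPRModel, val_features, val_labels):
    p = predict(model, val_features)
    return rmse(val_labels, p.mean), r2(val_labels, p.mean)


def _al_loop(pool_features, pool_labels, val_features, val_labels,
             init_n, seed, order: str):
    pool = np.atleast_2d(np.asarray(pool_features, dtype=float))
    labels = np.asarray(pool_labels, dtype=float)
    valf = np.atleast_2d(np.asarray(val_features, dtype=float))
    valy = np.asarray(val_labels, dtype=float)
    if valy.size < 2:
        raise ValidationError("validation set needs at least 2 samples")
    if pool.shape[1] != valf.shape[1]:
        raise DimensionError("pool/validation feature dimensions differ")
    n = pool.shape[0]
    if init_n < 2 or init_n > n:
        raise ValidationError(f"init_n={init_n!r} outside [2, pool size]")

    rng = np.random.default_rng(seed)
    selected = list(rng.choice(n, size=init_n, replace=False))
    remaining = [i for i in range(n) if i not in set(selected)]
    if order == "rs":
        rng.shuffle(remaining)

    model = train_gpr(pool[selected], labels[selected], seed=seed)
    best_rmse, best_r2 = _evaluate(model, valf, valy)
    state = ALState(selected_indices=list(selected),
                    rmse_trace=[best_rmse], r2_trace=[best_r2],
                    evaluated_count=0, seed=seed)
    incumbent = (model.signal_variance, model.lengthscales,
                 model.noise_variance)

    step = 0
    while remaining:
        if order == "ebd":
            local = ebd_next(pool[remaining], pool[selected])
            cand = remaining.pop(local)
        else:
            cand = remaining.pop(0)
        step += 1
        state.evaluated_count += 1

        trial = selected + [cand]
        # cheap screen: posterior refit at the incumbent hyperparameters
        screen = train_gpr(pool[trial], labels[trial], seed=seed,
                           init_hyperparameters=incumbent, optimize=False)
        cand_rmse, cand_r2 = _evaluate(screen, valf, valy)
        log_rmse, log_r2 = cand_rmse, cand_r2
        accepted = False
        if cand_rmse < best_rmse:
            # re-optimize hyperparameters from the incumbent and re-check, so
            # the recorded trace stays non-increasing under the final model
            refit = train_gpr(pool[trial], labels[trial], seed=seed,
                              init_hyperparameters=incumbent)
            refit_rmse, refit_r2 = _evaluate(refit, valf, valy)
            if refit_rmse < best_rmse:
                accepted = True
                selected = trial
                model = refit
                best_rmse, best_r2 = refit_rmse, refit_r2
                log_rmse, log_r2 = refit_rmse, refit_r2
                incumbent = (model.signal_variance, model.lengthscales,
                             model.noise_variance)
                state.selected_indices = list(selected)
                state.rmse_trace.append(best_rmse)
                state.r2_trace.append(best_r2)
        state.eval_log.append({"step": step, "pool_index": int(cand),
                               "accepted": accepted,
                               "rmse": log_rmse, "r2": log_r2})
    return state, model


def al_run(pool_features, pool_labels, val_features, val_labels,
           init_n: int = 10, seed: int = 0):
    """Diversity (max-min distance) pass over the pool; returns the state and
    the model trained on the accepted subset."""
    return _al_loop(pool_features, pool_labels, val_features, val_labels,
                    init_n, seed, order="ebd")


def rs_baseline(pool_features, pool_labels, val_features, val_labels,
                init_n: int = 10, seed: int = 0):
    """Random-order baseline with the identical accept/reject rule."""
    return _al_loop(pool_features, pool_labels, val_features, val_labels,
                    init_n, seed, order="rs")
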