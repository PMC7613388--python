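"""Gaussian-process regression with predictive uncertainty, plus metrics.

The kernel is an anisotropic squared exponential with additive white noise.
Labels are standardized internally; stored hyperparameters refer to the
standardized scale and are converted back at prediction time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .exceptions import DimensionError, UndefinedValueError, ValidationError

_LS_BOUNDS = (1e-3, 1e4)
_VAR_BOUNDS = (1e-6, 1e3)
_NOISE_BOUNDS = (1e-10, 1e1)


@dataclass
class GPRModel:
    """Trained Gaussian-process model (hyperparameters on standardized labels)."""

    signal_variance: float
    lengthscales: np.ndarray
    noise_variance: float
    training_features: np.ndarray
    training_labels: np.ndarray
    y_mean: float
    y_std: float
    log_marginal_likelihood: float
    seed: int
    _gp: GaussianProcessRegressor | None = field(default=None, repr=False,
                                                 compare=False)

    def __post_init__(self):
        if self.signal_variance <= 0 or self.noise_variance <= 0:
            raise ValidationError("kernel variances must be positive")
        if np.any(np.asarray(self.lengthscales) <= 0):
            raise ValidationError("lengthscales must be positive")
        if self.training_features.size == 0:
            raise ValidationError("training set is empty")
        if self.training_features.shape[0] != len(self.training_labels):
            raise DimensionError("features/labels row counts disagree")

    @property
    def kernel(self):
        return (ConstantKernel(self.signal_variance, "fixed")
                * RBF(self.lengthscales, "fixed")
                + WhiteKernel(self.noise_variance, "fixed"))

    def _fitted(self) -> GaussianProcessRegressor:
        if self._gp is None:
            gp = GaussianProcessRegressor(kernel=self.kernel, optimizer=None,
                                          alpha=0.0)
            z = (self.training_labels - self.y_mean) / self.y_std
            gp.fit(self.training_features, z)
            self._gp = gp
        return self._gp

    def save(self, path: str | Path) -> None:
        payload = {
            "signal_variance": self.signal_variance,
            "lengthscales": np.asarray(self.lengthscales).tolist(),
            "noise_variance": self.noise_variance,
            "training_features": self.training_features.tolist(),
            "training_labels": self.training_labels.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GPRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            signal_variance=d["signal_variance"],
            lengthscales=np.array(d["lengthscales"], dtype=float),
            noise_variance=d["noise_variance"],
            training_features=np.array(d["training_features"], dtype=float),
            training_labels=np.array(d["training_labels"], dtype=float),
            y_mean=d["y_mean"],
            y_std=d["y_std"],
            log_marginal_likelihood=d["log_marginal_likelihood"],
            seed=d["seed"],
        )


@dataclass(frozen=True)
class Prediction:
    """Per-query posterior mean, SD and coefficient of variation.

    ``cv`` is NaN wherever the mean is not strictly positive.
    """

    mean: np.ndarray
    sd: np.ndarray
    cv: np.ndarray


def train_gpr(features: np.ndarray, labels: np.ndarray, seed: int = 0,
              n_restarts: int = 3,
              init_hyperparameters: tuple | None = None,
              optimize: bool = True,
              min_lengthscale: float = 0.02) -> GPRModel:
    """Maximize the log marginal likelihood from a seeded multi-start.

    ``init_hyperparameters`` — optional ``(signal_var, lengthscales,
    noise_var)`` warm start (standardized-label scale); when given, a single
    optimizer run from that point replaces the multi-start.  With
    ``optimize=False`` the given hyperparameters are used as-is (only the
    posterior is recomputed).

    ``min_lengthscale`` — per-dimension floor on the kernel lengthscales.
    Noise-free simulated training data would otherwise drive lengthscales on
    the low-variance components to near zero, making every real (noisy) query
    look out-of-distribution.  The default suits reflectance-scale features
    with per-band noise of a few thousandths.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 training samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("features must be finite")
    if x.shape[0] != len(y):
        raise DimensionError("features/labels row counts disagree")

    y_mean = float(y.mean())
    y_std = float(y.std())
    degenerate = y_std <= 0.0
    if degenerate:
        warnings.warn("labels have zero variance; falling back to the prior "
                      "variance without hyperparameter optimization")
        y_std = 1.0
    z = (y - y_mean) / y_std

    d = x.shape[1]
    scale = x.std(axis=0)
    scale[scale <= 0] = 1.0
    # per-dimension lengthscale floor: the kernel may not become needle-thin
    # relative to the spread of that feature dimension, which would make every
    # slightly perturbed query look out-of-distribution
    floor = max(float(min_lengthscale), _LS_BOUNDS[0])
    ls_bounds = np.column_stack([np.maximum(scale / 30.0, floor),
                                 np.full(d, _LS_BOUNDS[1])])
    if init_hyperparameters is not None:
        sv, ls, nv = init_hyperparameters
        ls = np.clip(np.asarray(ls, dtype=float) * np.ones(d),
                     ls_bounds[:, 0], ls_bounds[:, 1])
        kernel = (ConstantKernel(float(sv), _VAR_BOUNDS)
                  * RBF(ls, ls_bounds)
                  + WhiteKernel(float(nv), _NOISE_BOUNDS))
        restarts = 0
    else:
        if not optimize:
            raise ValidationError(
                "optimize=False requires init_hyperparameters")
        init_ls = np.clip(scale, ls_bounds[:, 0], ls_bounds[:, 1])
        kernel = (ConstantKernel(1.0, _VAR_BOUNDS)
                  * RBF(init_ls, ls_bounds)
                  + WhiteKernel(1e-3, _NOISE_BOUNDS))
        restarts = max(int(n_restarts), 0)

    gp = GaussianProcessRegressor(
        kernel=kernel,
        optimizer=None if (degenerate or not optimize) else "fmin_l_bfgs_b",
        n_restarts_optimizer=restarts,
        alpha=0.0,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # flat likelihood directions routinely push ARD lengthscales to their
        # bounds; that is expected, not a failure
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(x, z)

    k = gp.kernel_
    model = GPRModel(
        signal_variance=float(k.k1.k1.constant_value),
        lengthscales=np.atleast_1d(np.array(k.k1.k2.length_scale, dtype=float)
                                   * np.ones(d)),
        noise_variance=float(k.k2.noise_level),
        training_features=x.copy(),
        training_labels=y.copy(),
        y_mean=y_mean,
        y_std=y_std,
        log_marginal_likelihood=float(gp.log_marginal_likelihood_value_),
        seed=seed,
    )
    model._gp = gp
    return model


def predict(model: GPRModel, features: np.ndarray) -> Prediction:
    """Closed-form posterior mean and SD per query row."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.training_features.shape[1]:
        raise DimensionError(
            f"query dimension {x.shape[1]} does not match model "
            f"dimension {model.training_features.shape[1]}")
    gp = model._fitted()
    z_mean, z_sd = gp.predict(x, return_std=True)
    mean = model.y_mean + model.y_std * z_mean
    sd = model.y_std * z_sd
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    return Prediction(mean=mean, sd=sd, cv=cv)


# ---------------------------------------------------------------------------
# goodness-of-fit metrics


def _check_pair(obs, est):
    obs = np.asarray(obs, dtype=float)
    est = np.asarray(est, dtype=float)
    if obs.shape != est.shape:
        raise DimensionError("obs and est must have equal length")
    if obs.size < 2:
        raise ValidationError("need at least 2 observations")
    return obs, est


def rmse(obs, est) -> float:
    """Root mean square error, label units."""
    obs, est = _check_pair(obs, est)
    return float(np.sqrt(np.mean((obs - est) ** 2)))


def r2(obs, est) -> float:
    """Coefficient of determination (1 - SSE / SST)."""
    obs, est = _check_pair(obs, est)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedValueError("r2 undefined for constant observations")
    return 1.0 - float(np.sum((obs - est) ** 2)) / sst


def nrmse(obs, est) -> float:
    """RMSE normalized by the observed range, in percent."""
    obs, est = _check_pair(obs, est)
    rng = float(obs.max() - obs.min())
    if rng == 0.0:
        raise UndefinedValueError("nrmse undefined for zero observed range")
    return 100.0 * rmse(obs, est) / rng
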