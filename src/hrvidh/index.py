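"""The HRV-IDH index: a logistic risk score for intradialytic hypotension.

The published model maps five night-time HRV parameters to a probability

    index = sigma(1.7394 + 0.1850*NN50 - 0.0344*TP + 0.0359*VLF
                  + 0.0341*LF - 0.2301*(LF:HF)),

with sigma the logistic function, the spectral powers in ms^2 and NN50 a
raw count.  Autonomic dysfunction is called at index >= 0.544 (any IDH) or
>= 0.576 (repeated IDH), both thresholds inclusive.  The module also
provides maximum-likelihood refitting (IRLS) and stepwise feature selection
for developing the same kind of index on new cohorts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .time_domain import HRVParams

#: Feature names in the fixed model order (keys of HRVParams fields).
INDEX_FEATURES = ("nn50", "tp", "vlf", "lf", "lf_hf_ratio")

ANY_IDH_CUTOFF = 0.544
REPEATED_IDH_CUTOFF = 0.576


class SeparationError(RuntimeError):
    """Maximum-likelihood logistic fit diverged: data are (quasi-)separable."""


@dataclass(frozen=True)
class LogisticIndexModel:
    intercept: float
    coefficients: Mapping[str, float]
    provenance: str = "refit"            # 'published' | 'refit'
    log_likelihood: Optional[float] = None
    converged: Optional[bool] = None
    std_errors: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        object.__setattr__(self, "coefficients",
                           MappingProxyType(dict(self.coefficients)))

    @property
    def feature_names(self) -> tuple:
        return tuple(self.coefficients.keys())

    def linear_predictor(self, features: Mapping[str, float]) -> float:
        eta = self.intercept
        for name, coef in self.coefficients.items():
            if name not in features or features[name] is None:
                raise ValueError(f"missing feature '{name}' for the index")
            x = float(features[name])
            if not math.isfinite(x):
                raise ValueError(f"feature '{name}' is not finite: {x}")
            eta += coef * x
        return eta

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "provenance": self.provenance,
            "cutoffs": {"any_idh": ANY_IDH_CUTOFF,
                        "repeated_idh": REPEATED_IDH_CUTOFF},
        }


#: The published HRV-IDH model (immutable; refits never overwrite it).
PUBLISHED_MODEL = LogisticIndexModel(
    intercept=1.7394,
    coefficients={
        "nn50": 0.1850,
        "tp": -0.0344,
        "vlf": 0.0359,
        "lf": 0.0341,
        "lf_hf_ratio": -0.2301,
    },
    provenance="published",
)


def hrv_idh_index(
    params: Union[HRVParams, Mapping[str, float]],
    model: LogisticIndexModel = PUBLISHED_MODEL,
) -> float:
    """Evaluate the logistic index for one HRV record; returns a probability
    strictly inside (0, 1)."""
    features = params.as_dict() if isinstance(params, HRVParams) else params
    eta = model.linear_predictor(features)
    # numerically stable sigmoid
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    z = math.exp(eta)
    return z / (1.0 + z)


def classify_dysfunction(index: float, cutoff: float = ANY_IDH_CUTOFF) -> bool:
    """Autonomic dysfunction flag: index >= cutoff (inclusive)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    if not 0.0 <= index <= 1.0:
        raise ValueError(f"index must be a probability, got {index}")
    return index >= cutoff


def _design(features: Union[pd.DataFrame, np.ndarray],
            names: Optional[Sequence[str]]) -> tuple[np.ndarray, list]:
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def fit_logistic(
    features: Union[pd.DataFrame, np.ndarray],
    labels: Sequence[int],
    feature_names: Optional[Sequence[str]] = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticIndexModel:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares.

    Converges when the largest coefficient update falls below ``tol`` (or
    after ``max_iter`` iterations, flagged unconverged).  Complete or
    quasi-complete separation raises :class:`SeparationError` rather than
    returning silently enormous coefficients.
    """
    X, names = _design(features, feature_names)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("features and labels disagree in length")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; cannot fit")
    n, p = X.shape
    if n < 10 * (p + 1):
        warnings.warn(f"only {n} observations for {p} predictors")

    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        if np.max(w) < 1e-10 or np.max(np.abs(eta)) > 500:
            _raise_if_separated(eta, y)
        wsafe = np.maximum(w, 1e-10)
        z = eta + (y - mu) / wsafe
        sw = np.sqrt(wsafe)
        beta_new, *_ = np.linalg.lstsq(Xd * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = Xd @ beta
    _raise_if_separated(eta, y)
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    eps = 1e-12
    ll = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    w = np.maximum(mu * (1 - mu), 1e-10)
    try:
        cov = np.linalg.inv(Xd.T @ (Xd * w[:, None]))
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.nan)
    return LogisticIndexModel(
        intercept=float(beta[0]),
        coefficients=dict(zip(names, beta[1:].tolist())),
        provenance="refit",
        log_likelihood=ll,
        converged=converged,
        std_errors=dict(zip(["intercept"] + names, se.tolist())),
    )


def _raise_if_separated(eta: np.ndarray, y: np.ndarray) -> None:
    """Diverging fit check: every fitted probability has collapsed onto its
    own label, which only happens when the data are (quasi-)separable and
    the ML estimate runs off to infinity."""
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    if np.all(np.abs(y - mu) < 1e-6):
        raise SeparationError(
            "complete separation detected: coefficients diverge"
        )


@dataclass
class SelectionResult:
    model: LogisticIndexModel
    selected: list
    path: list = field(default_factory=list)   # (step description) log


def select_features(
    candidates: Sequence[str],
    features: pd.DataFrame,
    labels: Sequence[int],
    strategy: str = "backward_p",
    p_threshold: float = 0.1,
) -> SelectionResult:
    """Backward stepwise selection over ``candidates``.

    ``backward_p`` drops, one at a time, the predictor with the largest Wald
    p-value above ``p_threshold``; ``aic`` drops whichever removal lowers
    AIC most, until no removal improves it.  The elimination path is logged
    in the result.
    """
    from scipy import stats

    if strategy not in ("backward_p", "aic"):
        raise ValueError(f"unknown selection strategy: {strategy!r}")
    current = list(candidates)
    path = []

    def _fit(cols):
        if cols:
            return fit_logistic(features[cols], labels)
        # intercept-only
        y = np.asarray(labels, dtype=float)
        pbar = float(np.mean(y))
        ll = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
        return LogisticIndexModel(
            intercept=float(np.log(pbar / (1 - pbar))), coefficients={},
            provenance="refit", log_likelihood=ll, converged=True)

    model = _fit(current)
    while current:
        if strategy == "backward_p":
            pvals = {}
            for name in current:
                se = model.std_errors[name]
                zval = model.coefficients[name] / se if se > 0 else 0.0
                pvals[name] = 2 * stats.norm.sf(abs(zval))
            worst = max(pvals, key=pvals.get)
            if pvals[worst] <= p_threshold:
                break
            current.remove(worst)
            path.append(f"drop {worst} (p={pvals[worst]:.3f})")
            model = _fit(current)
        else:  # aic
            aic_now = 2 * (len(current) + 1) - 2 * model.log_likelihood
            best_drop, best_aic, best_model = None, aic_now, model
            for name in current:
                trial = _fit([c for c in current if c != name])
                aic = 2 * len(current) - 2 * trial.log_likelihood
                if aic < best_aic:
                    best_drop, best_aic, best_model = name, aic, trial
            if best_drop is None:
                break
            current.remove(best_drop)
            path.append(f"drop {best_drop} (AIC {best_aic:.2f})")
            model = best_model
    return SelectionResult(model=model, selected=current, path=path)
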