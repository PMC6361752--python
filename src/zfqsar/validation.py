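"""Multilinear QSAR model fitting and every reported validation statistic.

Given a descriptor matrix X and k-value response y, this module fits
ordinary-least-squares models on descriptor subsets and computes the full
statistics block used to judge them: r2, adjusted r2, RMSE, the
leave-one-out PRESS and its q2, Friedman's lack-of-fit (LOF) score, the
overall regression F-test p-value, per-coefficient t-test p-values, and
external-test-set q2 / RMSE-EV.

Numerical conventions:

* RMSE uses the n-denominator, sqrt(SSE / n) - the convention under which
  the reported LOF is reconstructible from the reported RMSE;
* PRESS uses the hat-matrix identity PRESS = sum((e_i / (1 - h_ii))^2),
  algebraically equal to refitting with each sample left out;
* LOF = (SSE/n) / (1 - (c + d*p)/n)^2 with c the number of basis
  functions including the intercept, p the number of features and d a
  smoothing parameter defaulting to 0.5;
* external q2 follows the Q2-F1 convention (training-set mean in the
  denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .descriptors import DescriptorMatrix
from .errors import (
    DegreesOfFreedomError,
    LeakageError,
    LeverageError,
    OverParameterizedError,
    SingularDesignError,
)

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class LinearQSARModel:
    """A fitted linear model on a named descriptor subset."""

    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    training_ids: tuple[str, ...]

    def predict(self, X: DescriptorMatrix) -> np.ndarray:
        cols = np.column_stack([X.column(n) for n in self.descriptor_names])
        return self.intercept + cols @ np.asarray(self.coefficients)


@dataclass(frozen=True)
class ModelStats:
    """The statistics block for one fitted model."""

    r_squared: float
    r_squared_adj: float
    rmse: float
    press: float
    q_squared_loo: float
    lof: float
    p_regression: float
    coefficient_p_values: tuple[float, ...]


@dataclass(frozen=True)
class ExternalValidationStats:
    """External-test-set predictivity: Q2-F1 and RMSE-EV."""

    q_squared_ext: float
    rmse_ev: float
    n_test: int


def _design(X: DescriptorMatrix, subset: Sequence[str]) -> np.ndarray:
    cols = [X.column(name) for name in subset]
    return np.column_stack([np.ones(len(X.compound_ids))] + cols)


def _collinear_columns(design: np.ndarray, subset: Sequence[str]) -> tuple[str, ...]:
    """Columns linearly dependent on the ones before them (intercept first)."""
    offenders = []
    for j in range(1, design.shape[1]):
        sub = design[:, : j + 1]
        if np.linalg.matrix_rank(sub, tol=_RANK_TOL * max(1.0, np.abs(sub).max())) < j + 1:
            offenders.append(subset[j - 1])
    return tuple(offenders)


def fit_mlr(
    X: DescriptorMatrix, y: Sequence[float], subset: Sequence[str]
) -> LinearQSARModel:
    """Ordinary least squares with intercept on the named columns."""
    subset = list(subset)
    if len(set(subset)) != len(subset):
        dupes = tuple(sorted({s for s in subset if subset.count(s) > 1}))
        raise SingularDesignError(f"duplicated descriptors {dupes}", dupes)
    y = np.asarray(y, dtype=float)
    design = _design(X, subset)
    n, m1 = design.shape
    if m1 - 1 >= n - 1:
        raise DegreesOfFreedomError(
            f"{m1 - 1} descriptors with only {n} samples leaves no residual dof"
        )
    if np.linalg.matrix_rank(design, tol=_RANK_TOL * max(1.0, np.abs(design).max())) < m1:
        offenders = _collinear_columns(design, subset)
        raise SingularDesignError(
            f"rank-deficient design; collinear columns: {offenders}", offenders
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearQSARModel(
        descriptor_names=tuple(subset),
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        training_ids=tuple(X.compound_ids),
    )


def _hat_diagonal(design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    return np.sum(q * q, axis=1)


def press_q2(
    model: LinearQSARModel, X: DescriptorMatrix, y: Sequence[float]
) -> tuple[float, float]:
    """Leave-one-out PRESS via the hat-matrix identity, and q2 = 1 - PRESS/SST.

    The deleted residual for sample i is e_i / (1 - h_ii); any leverage of
    1 (a sample its own sole support) makes it undefined.
    """
    y = np.asarray(y, dtype=float)
    design = _design(X, model.descriptor_names)
    h = _hat_diagonal(design)
    near_one = np.nonzero(h >= 1.0 - 1e-12)[0]
    if near_one.size:
        bad = ", ".join(X.compound_ids[i] for i in near_one)
        raise LeverageError(f"leverage 1 for sample(s): {bad}")
    residuals = y - model.predict(X)
    press = float(np.sum((residuals / (1.0 - h)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / sst if sst > 0 else 1.0 if press == 0 else -np.inf
    return press, q2


def friedman_lof(
    sse: float,
    n_samples: int,
    n_basis_functions: int,
    n_features: int,
    smoothing_d: float = 0.5,
) -> float:
    """Friedman lack-of-fit: (SSE/n) / (1 - (c + d*p)/n)^2.

    c counts basis functions including the intercept; p counts features;
    d trades fit against model size (larger d punishes extra terms more).
    """
    if n_samples <= 0:
        raise OverParameterizedError("n_samples must be positive")
    penalty = (n_basis_functions + smoothing_d * n_features) / n_samples
    if penalty >= 1.0:
        raise OverParameterizedError(
            f"penalty fraction {penalty:.3f} >= 1 "
            f"(c={n_basis_functions}, d={smoothing_d}, p={n_features}, n={n_samples})"
        )
    return (sse / n_samples) / (1.0 - penalty) ** 2


def model_statistics(
    model: LinearQSARModel,
    X: DescriptorMatrix,
    y: Sequence[float],
    smoothing_d: float = 0.5,
) -> ModelStats:
    """The full statistics block for a model fitted on (X, y)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    m = len(model.descriptor_names)
    dof = n - m - 1
    if dof <= 0:
        raise DegreesOfFreedomError(f"n={n}, m={m}: no residual degrees of freedom")
    residuals = y - model.predict(X)
    sse = float(np.sum(residuals**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    rmse = float(np.sqrt(sse / n))
    press, q2 = press_q2(model, X, y)
    lof = friedman_lof(sse, n, m + 1, m, smoothing_d)
    # overall F test of the regression
    ssr = sst - sse
    if sse <= 0 or m == 0:
        p_regression = np.finfo(float).tiny if m else 1.0
    else:
        f_stat = (ssr / m) / (sse / dof)
        p_regression = float(stats.f.sf(f_stat, m, dof))
    # per-coefficient t tests (slopes only, matching the reported table)
    design = _design(X, model.descriptor_names)
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    beta = np.concatenate([[model.intercept], model.coefficients])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = beta / np.sqrt(np.diag(cov))
    p_coef = tuple(float(2.0 * stats.t.sf(abs(t), dof)) for t in t_stats[1:])
    return ModelStats(
        r_squared=r2,
        r_squared_adj=r2_adj,
        rmse=rmse,
        press=press,
        q_squared_loo=q2,
        lof=lof,
        p_regression=max(p_regression, np.finfo(float).tiny),
        coefficient_p_values=p_coef,
    )


def adjusted_r_squared(r_squared: float, n_samples: int, n_terms: int) -> float:
    """r2 adjusted for model size: 1 - (1 - r2)(n - 1)/(n - m - 1)."""
    dof = n_samples - n_terms - 1
    if dof <= 0:
        raise DegreesOfFreedomError(f"n={n_samples}, m={n_terms}")
    return 1.0 - (1.0 - r_squared) * (n_samples - 1) / dof


def external_validation(
    model: LinearQSARModel,
    X_test: DescriptorMatrix,
    y_test: Sequence[float],
    y_train_mean: float,
) -> ExternalValidationStats:
    """Predictivity on held-out compounds: Q2-F1 and RMSE-EV.

    Q2-F1 = 1 - sum((y - yhat)^2) / sum((y - ybar_train)^2), with the
    training-set mean in the denominator.
    """
    overlap = sorted(set(X_test.compound_ids) & set(model.training_ids))
    if overlap:
        raise LeakageError(f"test compounds seen in training: {overlap}")
    y_test = np.asarray(y_test, dtype=float)
    residuals = y_test - model.predict(X_test)
    sse = float(np.sum(residuals**2))
    denom = float(np.sum((y_test - y_train_mean) ** 2))
    q2_ext = 1.0 - sse / denom if denom > 0 else 1.0 if sse == 0 else -np.inf
    return ExternalValidationStats(
        q_squared_ext=q2_ext,
        rmse_ev=float(np.sqrt(sse / y_test.size)),
        n_test=int(y_test.size),
    )
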