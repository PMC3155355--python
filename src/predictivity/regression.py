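"""Multiple linear regression with leave-one-out validation and subset search.

The model-identification workflow for descriptor-based property models:
ordinary least squares with the full inference battery (coefficient t
statistics and 95% CIs, model F with its p-value, residual standard
error), leave-one-out cross-validation summarized by the predicted-vs-
observed correlation, and an exhaustive (or greedy, for large pools)
search over descriptor subsets ranked by the published multi-criteria
key: highest correlation coefficient, then fewest descriptors, then
lowest standard error, then smallest gap between the fit and LOO
correlation coefficients.

The F statistic follows the (k, n-k-1) convention:
F = (R^2 / k) / ((1 - R^2) / (n - k - 1)).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .synthetic import DescriptorMatrix

__all__ = [
    "MLRModel",
    "LOOResult",
    "ModelCandidate",
    "fit_mlr",
    "f_from_r2",
    "loo_cv",
    "durbin_watson",
    "search_models",
]


class SingularityError(ValueError):
    """The design matrix is rank deficient."""


@dataclass(frozen=True)
class MLRModel:
    """A fitted OLS model with its inference statistics.

    ``coefficients`` maps descriptor name -> slope; ``coef_half_widths``
    are 95% CI half-widths (estimate +/- half-width); ``t_values`` and
    ``t_ps`` include the intercept under the key ``"intercept"``.
    """

    intercept: float
    coefficients: dict[str, float]
    coef_half_widths: dict[str, float]
    r: float
    r2: float
    se_est: float
    f_value: float
    f_p: float
    t_values: dict[str, float]
    t_ps: dict[str, float]
    n: int
    k: int
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray | DescriptorMatrix) -> np.ndarray:
        if isinstance(X, DescriptorMatrix):
            X = X.select(list(self.coefficients)).values
        beta = np.array(list(self.coefficients.values()))
        return self.intercept + np.asarray(X, dtype=float) @ beta

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "coef_half_widths": self.coef_half_widths,
            "r": self.r, "r2": self.r2, "se_est": self.se_est,
            "f_value": self.f_value, "f_p": self.f_p,
            "t_values": self.t_values, "t_ps": self.t_ps,
            "n": self.n, "k": self.k,
        }


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out cross-validation summary.

    ``predictions[i]`` is the prediction for row i from the model fitted
    without row i; ``r_loo`` is the Pearson correlation between observed
    values and those held-out predictions; ``s_loo`` uses the same
    n-k-1 denominator as the fit standard error.
    """

    r_loo: float
    r2_loo: float
    s_loo: float
    f_loo: float
    f_loo_p: float
    predictions: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"r_loo": self.r_loo, "r2_loo": self.r2_loo, "s_loo": self.s_loo,
                "f_loo": self.f_loo, "f_loo_p": self.f_loo_p}


def _design(X, names=None):
    if isinstance(X, DescriptorMatrix):
        mat, names = X.values, list(X.names)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if names is None:
            names = [f"x{j + 1}" for j in range(mat.shape[1])]
    return mat, list(names)


def fit_mlr(
    X: DescriptorMatrix | np.ndarray,
    y: Sequence[float],
    names: Sequence[str] | None = None,
) -> MLRModel:
    """Ordinary least squares of y on the descriptor columns.

    R is the Pearson correlation between observed and fitted values,
    ``se_est`` the residual standard error on n-k-1 degrees of freedom,
    and the coefficient CIs are estimate +/- t(0.975, n-k-1) * SE.
    """
    mat, names = _design(X, names)
    y = np.asarray(y, dtype=float)
    n, k = mat.shape
    if len(y) != n:
        raise ValueError(f"response length {len(y)} != {n} rows")
    if n <= k + 1:
        raise ValueError(f"need n > k+1, got n={n}, k={k}")
    A = np.column_stack([np.ones(n), mat])
    rank = np.linalg.matrix_rank(A)
    if rank < k + 1:
        # Identify offending columns by incremental rank growth.
        bad = []
        cur = A[:, :1]
        for j in range(k):
            trial = np.column_stack([cur, mat[:, j]])
            if np.linalg.matrix_rank(trial) == cur.shape[1]:
                bad.append(names[j])
            else:
                cur = trial
        raise SingularityError(f"design matrix is rank deficient; dependent columns: {bad}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ beta
    resid = y - fitted
    dof = n - k - 1
    sse = float(resid @ resid)
    se_est = math.sqrt(sse / dof)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    # R as the observed-vs-fitted Pearson correlation (equals sqrt(R^2)
    # for OLS with intercept, up to rounding).
    if np.std(fitted) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(y, fitted)[0, 1])
    else:
        r = 0.0
    xtx_inv = np.linalg.inv(A.T @ A)
    if se_est > 0:
        se_beta = se_est * np.sqrt(np.diag(xtx_inv))
        t_vals = beta / se_beta
        t_p = 2 * stats.t.sf(np.abs(t_vals), dof)
    else:
        se_beta = np.zeros_like(beta)
        t_vals = np.where(beta != 0, np.inf, 0.0)
        t_p = np.where(beta != 0, 0.0, 1.0)
    tcrit = stats.t.ppf(0.975, dof)
    f_value, f_p = f_from_r2(r2, n, k)
    keys = ["intercept"] + names
    return MLRModel(
        intercept=float(beta[0]),
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        coef_half_widths={nm: float(tcrit * s) for nm, s in zip(names, se_beta[1:])},
        r=r,
        r2=r2,
        se_est=se_est,
        f_value=f_value,
        f_p=f_p,
        t_values={kk: float(t) for kk, t in zip(keys, t_vals)},
        t_ps={kk: float(p) for kk, p in zip(keys, t_p)},
        n=n,
        k=k,
        fitted=fitted,
        residuals=resid,
    )


def f_from_r2(r2: float, n: int, k: int) -> tuple[float, float]:
    """F statistic (and p-value) from a determination coefficient.

    F = (R^2 / k) / ((1 - R^2) / (n - k - 1)) on (k, n-k-1) degrees of
    freedom; R^2 = 1 returns infinity with p = 0.
    """
    if not 0 <= r2 <= 1:
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k+1, got n={n}, k={k}")
    if r2 == 1.0:
        return math.inf, 0.0
    f = (r2 / k) / ((1 - r2) / (n - k - 1))
    return f, float(stats.f.sf(f, k, n - k - 1))


def loo_cv(
    X: DescriptorMatrix | np.ndarray,
    y: Sequence[float],
    names: Sequence[str] | None = None,
) -> LOOResult:
    """Leave-one-out cross-validation of the OLS fit.

    Each observation is predicted from the model fitted to the remaining
    n-1 rows; for OLS this equals the hat-matrix identity
    y_i - e_i / (1 - h_ii), which is used here (the explicit refit loop
    gives identical numbers).  ``r_loo`` is the Pearson correlation of
    observed values with the held-out predictions and
    ``s_loo = sqrt(PRESS / (n - k - 1))``.
    """
    mat, names = _design(X, names)
    y = np.asarray(y, dtype=float)
    n, k = mat.shape
    if n <= k + 2:
        raise ValueError(f"need n > k+2 for leave-one-out, got n={n}, k={k}")
    model = fit_mlr(mat, y, names)
    A = np.column_stack([np.ones(n), mat])
    h = np.einsum("ij,jk,ik->i", A, np.linalg.inv(A.T @ A), A)
    if np.any(h >= 1 - 1e-12):
        row = int(np.argmax(h))
        raise SingularityError(f"leave-one-out refit singular without row {row}")
    press_resid = model.residuals / (1 - h)
    predictions = y - press_resid
    press = float(press_resid @ press_resid)
    s_loo = math.sqrt(press / (n - k - 1))
    if np.std(predictions) > 0:
        r_loo = float(np.corrcoef(y, predictions)[0, 1])
    else:
        r_loo = 0.0
    r2_loo = r_loo**2
    f_loo, f_loo_p = f_from_r2(r2_loo, n, k)
    return LOOResult(r_loo=r_loo, r2_loo=r2_loo, s_loo=s_loo,
                     f_loo=f_loo, f_loo_p=f_loo_p, predictions=predictions)


def durbin_watson(residuals: Sequence[float]) -> float:
    """Autocorrelation diagnostic: sum of squared successive differences
    of the residuals over their sum of squares (values near 2 indicate no
    first-order autocorrelation)."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(e @ e)
    if denom == 0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


@dataclass(frozen=True)
class ModelCandidate:
    """One descriptor subset with its fit, LOO summary and ranking key."""

    descriptor_names: tuple[str, ...]
    model: MLRModel
    loo: LOOResult
    rank_key: tuple

    def to_dict(self) -> dict:
        return {
            "descriptors": list(self.descriptor_names),
            "model": self.model.to_dict(),
            "loo": self.loo.to_dict(),
        }


def _rank_key(model: MLRModel, loo: LOOResult) -> tuple:
    # Lexicographic: R (4 d.p., descending), fewer descriptors, lower
    # standard error, smaller |R - R_loo|.  Rounding R keeps float noise
    # from reordering effectively tied candidates.
    return (-round(model.r, 4), model.k, model.se_est, abs(model.r - loo.r_loo))


def search_models(
    X: DescriptorMatrix,
    y: Sequence[float],
    max_k: int = 4,
    greedy_threshold: int = 25,
) -> list[ModelCandidate]:
    """Search descriptor subsets and rank them by the selection criteria.

    Exhaustive over all subsets of size 1..max_k when the pool has at
    most ``greedy_threshold`` columns; otherwise greedy forward selection
    evaluated with the same ranking key.  Candidates are ordered by
    (highest R to 4 decimals, fewest descriptors, lowest standard error
    of estimate, smallest |R - R_loo|); the order is deterministic.
    """
    y = np.asarray(y, dtype=float)
    candidates: list[ModelCandidate] = []

    def evaluate(names: tuple[str, ...]) -> ModelCandidate | None:
        sub = X.select(list(names))
        try:
            model = fit_mlr(sub, y)
            loo = loo_cv(sub, y)
        except (SingularityError, ValueError):
            return None
        return ModelCandidate(names, model, loo, _rank_key(model, loo))

    if X.m <= greedy_threshold:
        for k in range(1, max_k + 1):
            for combo in itertools.combinations(X.names, k):
                cand = evaluate(combo)
                if cand is not None:
                    candidates.append(cand)
    else:
        selected: tuple[str, ...] = ()
        while len(selected) < max_k:
            step = [c for nm in X.names if nm not in selected
                    if (c := evaluate(selected + (nm,))) is not None]
            if not step:
                break
            best = min(step, key=lambda c: c.rank_key)
            candidates.extend(step)
            selected = best.descriptor_names
    if not candidates:
        raise SingularityError("no descriptor subset produced a valid fit")
    candidates.sort(key=lambda c: (c.rank_key, c.descriptor_names))
    return candidates
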