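"""Observed-vs-estimated correlation battery and correlation comparison.

Seven coefficients are reported for each observed/estimated property pair:
Pearson r, a semi-quantitative coefficient r_sQ (value-vs-rank; pluggable,
see :data:`RSQ_STRATEGIES`), Spearman rho, Kendall's tau-a, tau-b and
tau-c (Stuart), and the Goodman-Kruskal Gamma.  Two fitted models are
compared on their correlation coefficients with the two-independent-
samples Fisher-z test; the dependent-correlations (shared-sample) variant
is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationSuite",
    "ComparisonResult",
    "correlation_suite",
    "compare_correlations",
    "compare_dependent_correlations",
    "concordance_counts",
    "RSQ_STRATEGIES",
]


def concordance_counts(x: Sequence[float], y: Sequence[float]) -> tuple[int, int, int, int, int]:
    """Count pair relations between two vectors.

    Returns (C, D, Tx, Ty, Txy): concordant pairs, discordant pairs,
    pairs tied only in x, tied only in y, and tied in both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    c = d = tx = ty = txy = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                txy += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                c += 1
            else:
                d += 1
    return c, d, tx, ty, txy


def _rsq_value_vs_rank(obs: np.ndarray, est: np.ndarray) -> float:
    """Pearson correlation of observed values with mid-ranks of estimates."""
    return float(stats.pearsonr(obs, stats.rankdata(est)).statistic)


def _rsq_geometric(obs: np.ndarray, est: np.ndarray) -> float:
    r = float(stats.pearsonr(obs, est).statistic)
    rho = float(stats.spearmanr(obs, est).statistic)
    sign = math.copysign(1.0, r)
    return sign * math.sqrt(abs(r * rho))


RSQ_STRATEGIES: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "value_vs_rank": _rsq_value_vs_rank,
    "geometric_mean": _rsq_geometric,
}
"""Available definitions of the semi-quantitative coefficient r_sQ.

No authoritative closed form exists for r_sQ; the default
``"value_vs_rank"`` correlates the observed values with the mid-ranks of
the estimates (a coefficient intermediate between Pearson r and Spearman
rho), and alternates can be plugged in here.
"""


@dataclass(frozen=True)
class CorrelationSuite:
    """The seven observed-vs-estimated coefficients with p-values."""

    r: float
    r_p: float
    rsq_semi: float
    rho: float
    rho_p: float
    tau_a: float
    tau_a_p: float
    tau_b: float
    tau_b_p: float
    tau_c: float
    tau_c_p: float
    gamma: float
    gamma_p: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def correlation_suite(
    observed: Sequence[float],
    estimated: Sequence[float],
    rsq_strategy: str = "value_vs_rank",
) -> CorrelationSuite:
    """Compute the full correlation battery between two paired vectors.

    tau-a divides C - D by all n(n-1)/2 pairs; tau-b applies the usual
    tie corrections; tau-c is Stuart's 2(C-D)*min(w_x, w_y) /
    (n^2 (min-1)) with w the number of distinct values per vector;
    Gamma = (C-D)/(C+D).  p-values: t-test for r and rho, tie-corrected
    normal approximation for the tau family, Goodman-Kruskal asymptotic
    normal approximation for Gamma.
    """
    obs = np.asarray(observed, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if obs.shape != est.shape or obs.ndim != 1:
        raise ValueError("observed and estimated must be equal-length 1-d vectors")
    n = len(obs)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(obs) == 0 or np.ptp(est) == 0:
        raise ValueError("rank correlations undefined for a constant vector")

    pear = stats.pearsonr(obs, est)
    spear = stats.spearmanr(obs, est)

    c, d, tx, ty, txy = concordance_counts(obs, est)
    n_pairs = n * (n - 1) // 2
    tau_a = (c - d) / n_pairs
    # Normal approximation for tau-a under the null (no-tie variance).
    var_a = (2 * (2 * n + 5)) / (9 * n * (n - 1))
    tau_a_p = 2 * stats.norm.sf(abs(tau_a) / math.sqrt(var_a))

    ktb = stats.kendalltau(obs, est, variant="b")
    ktc = stats.kendalltau(obs, est, variant="c")

    if c + d == 0:
        raise ValueError("Gamma undefined: no untied pairs")
    gamma = (c - d) / (c + d)
    # Goodman-Kruskal asymptotic: se under H0 ~ sqrt(n(1-gamma^2)/(C+D)).
    if abs(gamma) < 1:
        z_g = gamma * math.sqrt((c + d) / (n * (1 - gamma**2)))
        gamma_p = 2 * stats.norm.sf(abs(z_g))
    else:
        gamma_p = 0.0

    rsq = RSQ_STRATEGIES[rsq_strategy](obs, est)
    return CorrelationSuite(
        r=float(pear.statistic),
        r_p=float(pear.pvalue),
        rsq_semi=rsq,
        rho=float(spear.statistic),
        rho_p=float(spear.pvalue),
        tau_a=tau_a,
        tau_a_p=float(tau_a_p),
        tau_b=float(ktb.statistic),
        tau_b_p=float(ktb.pvalue),
        tau_c=float(ktc.statistic),
        tau_c_p=float(ktc.pvalue),
        gamma=gamma,
        gamma_p=float(gamma_p),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Fisher-z comparison of two correlation coefficients."""

    z: float
    p_one_sided: float
    r1: float
    n1: int
    r2: float
    n2: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> ComparisonResult:
    """Compare two correlations from independent samples.

    Z = (atanh(r2) - atanh(r1)) / sqrt(1/(n1-3) + 1/(n2-3)); the reported
    p is the one-sided upper-tail probability of |Z|.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
        if n <= 3:
            raise ValueError(f"need n > 3, got {n}")
    se = math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    z = (math.atanh(r2) - math.atanh(r1)) / se
    return ComparisonResult(z=z, p_one_sided=float(stats.norm.sf(abs(z))),
                            r1=r1, n1=n1, r2=r2, n2=n2)


def compare_dependent_correlations(
    r12: float, r13: float, r23: float, n: int
) -> ComparisonResult:
    """Compare two correlations sharing one variable on the same sample
    (the dependent-correlations Z of Steiger, with the mean-correlation
    simplification).  Not used in the published comparisons, which are
    between disjoint samples; provided for completeness."""
    for r in (r12, r13):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1, got {r}")
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    rbar = (r12 + r13) / 2
    det = (1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23)
    cov = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
    denom = (1 - rbar**2) ** 2
    z = (math.atanh(r12) - math.atanh(r13)) * math.sqrt(
        (n - 3) / (2 * (1 - cov / denom))
    )
    return ComparisonResult(z=z, p_one_sided=float(stats.norm.sf(abs(z))),
                            r1=r12, n1=n, r2=r13, n2=n)
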