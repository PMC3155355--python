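"""Contingency-table predictivity diagnostics for binary classification models.

A continuous property (here logBB, the log10 brain:blood concentration
ratio) is dichotomized into active / inactive classes, observed and
model-estimated labels are cross-tabulated into a 2x2 table, and the table
is summarized by fifteen diagnostic parameters (accuracy, error rate, class
prior probabilities, sensitivity/specificity and their complements,
positive/negative predictivity, post-test classification probabilities,
probabilities of wrong classification, odds ratio) together with the
Yates-corrected chi-squared statistic and the association coefficient
Phi = sqrt(chi2 / n).  Every proportion-type parameter carries a 95%
binomial confidence interval.

Scale conventions: accuracy, error rate, Se, FNR, Sp, FPR, PP and NP are
reported in percent; the prior and post-test probabilities and the
probabilities of wrong classification are reported on the probability
scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

ACTIVE = "active"
INACTIVE = "inactive"

__all__ = [
    "ContingencyTable",
    "ProportionCI",
    "DiagnosticReport",
    "dichotomize",
    "build_table",
    "diagnose",
    "chi2_yates",
    "binomial_ci",
    "reconstruct_table",
    "render_report",
]


class ZeroMarginError(ValueError):
    """A table margin needed by the requested statistic is zero."""


class ReconstructionError(ValueError):
    """No integer table is consistent with the printed summary values."""


def dichotomize(logbb: Sequence[float], threshold: float = 0.0) -> list[str]:
    """Binarize a continuous property: value >= threshold -> ``"active"``.

    The boundary itself is active, so a compound with logBB exactly 0 is a
    blood-brain-barrier penetrator (BBB+).
    """
    arr = np.asarray(logbb, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logbb values must be finite")
    return [ACTIVE if v >= threshold else INACTIVE for v in arr]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-tabulation of observed vs predicted class labels.

    ``tp``: observed-active predicted-active, ``fp``: observed-inactive
    predicted-active, ``fn``: observed-active predicted-inactive, ``tn``:
    observed-inactive predicted-inactive.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def observed_active(self) -> int:
        return self.tp + self.fn

    @property
    def observed_inactive(self) -> int:
        return self.fp + self.tn

    @property
    def predicted_active(self) -> int:
        return self.tp + self.fp

    @property
    def predicted_inactive(self) -> int:
        return self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


def build_table(observed: Sequence[str], predicted: Sequence[str]) -> ContingencyTable:
    """Count the four cells from parallel observed / predicted label vectors."""
    if len(observed) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(observed)} observed vs {len(predicted)} predicted"
        )
    tp = fp = fn = tn = 0
    for o, p in zip(observed, predicted):
        if o == ACTIVE:
            if p == ACTIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == ACTIVE:
                fp += 1
            else:
                tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its two-sided confidence interval."""

    estimate: float
    lower: float
    upper: float
    method: str = "clopper_pearson"
    alpha: float = 0.05

    def scaled(self, factor: float) -> "ProportionCI":
        return ProportionCI(
            self.estimate * factor, self.lower * factor, self.upper * factor,
            self.method, self.alpha,
        )


_CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson"}


def binomial_ci(
    k: int, n: int, alpha: float = 0.05, method: str = "clopper_pearson"
) -> ProportionCI:
    """Confidence interval for a binomial proportion k/n.

    ``method`` is ``"clopper_pearson"`` (exact, beta quantiles — the
    default) or ``"wilson"`` (score interval).
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    try:
        sm_method = _CI_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown CI method {method!r}") from None
    lower, upper = proportion_confint(k, n, alpha=alpha, method=sm_method)
    return ProportionCI(k / n, float(lower), float(upper), method, alpha)


def chi2_yates(t: ContingencyTable) -> tuple[float, float]:
    """Yates continuity-corrected chi-squared statistic and p-value (1 df).

    chi2 = n * (max(0, |tp*tn - fp*fn| - n/2))^2 / product(margins).
    The correction is clamped at zero so near-independent tables cannot
    yield a spurious positive statistic.
    """
    margins = (
        t.predicted_active, t.predicted_inactive, t.observed_active, t.observed_inactive
    )
    if any(m == 0 for m in margins):
        raise ZeroMarginError("chi-squared undefined: a table margin is zero")
    num = t.n * max(0.0, abs(t.tp * t.tn - t.fp * t.fn) - t.n / 2.0) ** 2
    statistic = num / math.prod(margins)
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def _safe_ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def _ci_or_none(k: int, den: int, alpha: float, method: str) -> ProportionCI | None:
    if den == 0:
        return None
    return binomial_ci(k, den, alpha=alpha, method=method)


@dataclass(frozen=True)
class DiagnosticReport:
    """The full diagnostic battery for one 2x2 table.

    Percent-scale fields: ``ac``, ``er``, ``se``, ``fnr``, ``sp``, ``fpr``,
    ``pp``, ``np_`` (negative predictivity).  Probability-scale fields:
    ``ppp_active``, ``ppp_inactive``, ``pca``, ``pcic``, ``pwca``, ``pwci``.
    Fields whose denominator is zero are ``None`` (rendered "n.a."), as is
    the odds ratio when fp*fn = 0.
    """

    table: ContingencyTable
    ac: float
    er: float
    ppp_active: float
    ppp_inactive: float
    se: float | None
    fnr: float | None
    sp: float | None
    fpr: float | None
    pp: float | None
    np_: float | None
    pca: float
    pcic: float
    pwca: float | None
    pwci: float | None
    or_: float | None
    or_ci: tuple[float, float] | None
    chi2: float | None
    chi2_p: float | None
    phi: float | None
    cis: Mapping[str, ProportionCI | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def ci(name):
            c = self.cis.get(name)
            return None if c is None else [c.lower, c.upper]

        t = self.table
        return {
            "cells": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
            "n": t.n,
            "chi2": self.chi2,
            "chi2_p": self.chi2_p,
            "phi": self.phi,
            "ac": {"value": self.ac, "ci": ci("ac")},
            "er": {"value": self.er},
            "ppp_active": {"value": self.ppp_active, "ci": ci("ppp_active")},
            "ppp_inactive": {"value": self.ppp_inactive, "ci": ci("ppp_inactive")},
            "se": {"value": self.se, "ci": ci("se")},
            "fnr": {"value": self.fnr, "ci": ci("fnr")},
            "sp": {"value": self.sp, "ci": ci("sp")},
            "fpr": {"value": self.fpr, "ci": ci("fpr")},
            "pp": {"value": self.pp, "ci": ci("pp")},
            "np": {"value": self.np_, "ci": ci("np")},
            "pca": {"value": self.pca, "ci": ci("pca")},
            "pcic": {"value": self.pcic, "ci": ci("pcic")},
            "pwca": {"value": self.pwca, "ci": ci("pwca")},
            "pwci": {"value": self.pwci, "ci": ci("pwci")},
            "or": {"value": self.or_, "ci": list(self.or_ci) if self.or_ci else None},
        }


def diagnose(
    t: ContingencyTable,
    alpha: float = 0.05,
    ci_method: str = "clopper_pearson",
) -> DiagnosticReport:
    """Compute the full diagnostic parameter battery for a 2x2 table.

    Each parameter is the literal cell-count ratio; percentages are 100x
    the proportion.  Confidence intervals are binomial intervals on the
    underlying proportion (``ci_method``), scaled to match the parameter's
    reporting scale.  The odds-ratio interval is the log-scale Wald
    interval exp(ln OR +/- z * sqrt(1/tp + 1/fp + 1/fn + 1/tn)).
    """
    n = t.n
    oa, oi = t.observed_active, t.observed_inactive
    pa, pi = t.predicted_active, t.predicted_inactive

    ac_prop = (t.tp + t.tn) / n
    se_prop = _safe_ratio(t.tp, oa)
    sp_prop = _safe_ratio(t.tn, oi)
    pp_prop = _safe_ratio(t.tp, pa)
    np_prop = _safe_ratio(t.tn, pi)
    pwca = _safe_ratio(t.fp, pa)
    pwci = _safe_ratio(t.fn, pi)

    if t.fp * t.fn > 0 and t.tp * t.tn > 0:
        or_ = (t.tp * t.tn) / (t.fp * t.fn)
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * math.sqrt(1 / t.tp + 1 / t.fp + 1 / t.fn + 1 / t.tn)
        or_ci = (or_ * math.exp(-half), or_ * math.exp(half))
    else:
        or_, or_ci = None, None

    try:
        chi2, chi2_p = chi2_yates(t)
        phi = math.sqrt(chi2 / n)
    except ZeroMarginError:
        chi2 = chi2_p = phi = None

    def pct_ci(k, den):
        c = _ci_or_none(k, den, alpha, ci_method)
        return None if c is None else c.scaled(100.0)

    cis = {
        "ac": pct_ci(t.tp + t.tn, n),
        "ppp_active": _ci_or_none(oa, n, alpha, ci_method),
        "ppp_inactive": _ci_or_none(oi, n, alpha, ci_method),
        "se": pct_ci(t.tp, oa),
        "fnr": pct_ci(t.fn, oa),
        "sp": pct_ci(t.tn, oi),
        "fpr": pct_ci(t.fp, oi),
        "pp": pct_ci(t.tp, pa),
        "np": pct_ci(t.tn, pi),
        "pca": _ci_or_none(pa, n, alpha, ci_method),
        "pcic": _ci_or_none(pi, n, alpha, ci_method),
        "pwca": _ci_or_none(t.fp, pa, alpha, ci_method),
        "pwci": _ci_or_none(t.fn, pi, alpha, ci_method),
    }

    def pct(p):
        return None if p is None else 100.0 * p

    return DiagnosticReport(
        table=t,
        ac=100.0 * ac_prop,
        er=100.0 * (1 - ac_prop),
        ppp_active=oa / n,
        ppp_inactive=oi / n,
        se=pct(se_prop),
        fnr=pct(None if se_prop is None else 1 - se_prop),
        sp=pct(sp_prop),
        fpr=pct(None if sp_prop is None else 1 - sp_prop),
        pp=pct(pp_prop),
        np_=pct(np_prop),
        pca=pa / n,
        pcic=pi / n,
        pwca=pwca,
        pwci=pwci,
        or_=or_,
        or_ci=or_ci,
        chi2=chi2,
        chi2_p=chi2_p,
        phi=phi,
        cis=cis,
    )


def reconstruct_table(
    n: int, prevalence: float, se_pct: float, sp_pct: float
) -> ContingencyTable:
    """Recover the integer 2x2 table behind published summary values.

    ``prevalence`` is the observed-active fraction as printed (3 decimals),
    ``se_pct`` / ``sp_pct`` are sensitivity and specificity in percent as
    printed (2 decimals).  Enumerates every integer table of total ``n``
    whose summaries match the printed values to within one unit in the
    last printed place for the prevalence (published priors are
    occasionally off by one in the final digit) and half a unit for Se
    and Sp, and returns the unique match (ties broken by minimal squared
    rounding distance).  Raises
    :class:`ReconstructionError`, listing the nearest candidates, when no
    table is consistent.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    # The three printed summaries constrain disjoint cells: prevalence fixes
    # the observed-active margin oa = tp + fn, Se depends only on tp given
    # oa, Sp only on tn.  Each can therefore be searched independently.
    matches: list[tuple[float, ContingencyTable]] = []
    eps = 1e-9  # guards exact half-ulp boundaries against binary rounding
    for oa in range(1, n):
        d_prev = abs(oa / n - prevalence)
        if d_prev > 0.001 + eps:
            continue
        oi = n - oa
        tps = [(abs(100 * tp / oa - se_pct), tp) for tp in range(oa + 1)
               if abs(100 * tp / oa - se_pct) <= 0.005 + eps]
        tns = [(abs(100 * tn / oi - sp_pct), tn) for tn in range(oi + 1)
               if abs(100 * tn / oi - sp_pct) <= 0.005 + eps]
        for d_se, tp in tps:
            for d_sp, tn in tns:
                dist = d_prev**2 + (d_se / 100) ** 2 + (d_sp / 100) ** 2
                matches.append((dist, ContingencyTable(tp, oi - tn, oa - tp, tn)))
    if not matches:
        oa = max(1, min(n - 1, round(prevalence * n)))
        oi = n - oa
        tp = min(range(oa + 1), key=lambda t_: abs(100 * t_ / oa - se_pct))
        tn = min(range(oi + 1), key=lambda t_: abs(100 * t_ / oi - sp_pct))
        raise ReconstructionError(
            f"no table of n={n} matches prevalence={prevalence}, Se={se_pct}, "
            f"Sp={sp_pct}; nearest candidate: (tp={tp}, fp={oi - tn}, "
            f"fn={oa - tp}, tn={tn})"
        )
    matches.sort(key=lambda x: x[0])
    return matches[0][1]


_ROWS: tuple[tuple[str, str, str], ...] = (
    # (key, label, scale) in published row order
    ("chi2", "Chi-squared (p)", "chi2"),
    ("phi", "Phi", "raw4"),
    ("ac", "Accuracy (AC)", "pct"),
    ("er", "Error rate (ER)", "pct"),
    ("ppp_active", "Prior probability, active (PPP+)", "prob"),
    ("ppp_inactive", "Prior probability, inactive (PPP-)", "prob"),
    ("se", "Sensitivity (Se)", "pct"),
    ("fnr", "False-negative rate (FNR)", "pct"),
    ("sp", "Specificity (Sp)", "pct"),
    ("fpr", "False-positive rate (FPR)", "pct"),
    ("pp", "Positive predictivity (PP)", "pct"),
    ("np", "Negative predictivity (NP)", "pct"),
    ("pca", "Post-test P(classified active) (PCA)", "prob"),
    ("pcic", "Post-test P(classified inactive) (PCIC)", "prob"),
    ("pwca", "P(wrong classification as active) (PWCA)", "prob"),
    ("pwci", "P(wrong classification as inactive) (PWCI)", "prob"),
    ("or", "Odds ratio (OR)", "or"),
)


def render_report(reports: Mapping[str, DiagnosticReport]) -> str:
    """Format one or more diagnostic reports as an aligned text table.

    One column per report (named by its mapping key), rows in the
    published order; percents to 2 decimals with CI in brackets,
    probabilities to 3 decimals; undefined entries print "n.a.".
    """
    if not reports:
        raise ValueError("need at least one report")
    dicts = {name: r.to_dict() for name, r in reports.items()}

    def fmt(d: dict, key: str, scale: str) -> str:
        if scale == "chi2":
            if d["chi2"] is None:
                return "n.a."
            return f"{d['chi2']:.2f} ({d['chi2_p']:.4f})"
        if scale == "raw4":
            return "n.a." if d["phi"] is None else f"{d['phi']:.4f}"
        entry = d[key]
        v, ci = entry["value"], entry.get("ci")
        if v is None:
            return "n.a."
        prec = 2 if scale in ("pct", "or") else 3
        out = f"{v:.{prec}f}"
        if ci:
            out += f" [{ci[0]:.{prec}f}-{ci[1]:.{prec}f}]"
        return out

    names = list(dicts)
    header = ["Parameter"] + [f"{nm} (n={dicts[nm]['n']})" for nm in names]
    lines = [[label] + [fmt(dicts[nm], key, scale) for nm in names]
             for key, label, scale in _ROWS]
    widths = [max(len(row[i]) for row in [header] + lines) for i in range(len(header))]
    def join(row):
        return "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
    sep = "-" * (sum(widths) + 2 * (len(widths) - 1))
    return "\n".join([join(header), sep] + [join(r) for r in lines])


def reports_to_json(reports: Mapping[str, DiagnosticReport], **kwargs) -> str:
    """Serialize a named set of diagnostic reports to JSON."""
    return json.dumps({k: r.to_dict() for k, r in reports.items()}, **kwargs)
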