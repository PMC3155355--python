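"""Compound property tables: loading, validation, splitting, summarizing.

The packaged fixture ``"table4"`` is the 122-compound blood-brain-barrier
permeation dataset (observed logBB with a training/test assignment:
81 training, 41 test) used throughout the worked examples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SET_LABELS = ("training", "test", "external")

__all__ = [
    "PropertyRecord",
    "SetSummary",
    "load_property_table",
    "summarize_set",
    "random_split",
]


class FormatError(ValueError):
    """The property table is malformed (missing columns, bad values)."""


@dataclass(frozen=True)
class PropertyRecord:
    """One compound: identifier, name, observed logBB and set assignment."""

    compound_id: str
    name: str
    logbb: float
    set_label: str
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not math.isfinite(self.logbb):
            raise ValueError(f"logbb must be finite for {self.compound_id}")
        if self.set_label not in SET_LABELS:
            raise ValueError(
                f"set_label must be one of {SET_LABELS}, got {self.set_label!r}"
            )


@dataclass(frozen=True)
class SetSummary:
    """Descriptive statistics and normality diagnostics for one subset.

    ``ks_stat``/``ks_p``: Kolmogorov-Smirnov statistic against a normal
    with the subset's own moment estimates; ``ad_stat``: Anderson-Darling
    A-squared; ``cs_stat``/``cs_p``: chi-squared goodness-of-fit with
    Sturges binning; ``jb_stat``: Jarque-Bera.
    """

    n: int
    mean: float
    mean_ci: tuple[float, float]
    stdev: float
    min: float
    max: float
    ks_stat: float
    ks_p: float
    ad_stat: float
    cs_stat: float
    cs_p: float
    jb_stat: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def load_property_table(path_or_builtin: str | Path) -> list[PropertyRecord]:
    """Read a compound property table from CSV (or the packaged fixture).

    The CSV must have header columns ``id``, ``name``, ``logbb``, ``set``
    (an optional ``ref`` column is carried through as ``source_ref``).
    ``set`` accepts the labels ``training``/``test``/``external`` or the
    published numeric codes 1/2.  The builtin token ``"table4"`` loads the
    packaged 122-compound logBB fixture.
    """
    if str(path_or_builtin) == "table4":
        source = resources.files("predictivity.data").joinpath("table4.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        path = Path(path_or_builtin)
        if path.stat().st_size == 0:
            raise FormatError(f"{path}: empty file")
        df = pd.read_csv(path, dtype=str)
    missing = {"id", "name", "logbb", "set"} - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")
    if df.empty:
        raise FormatError("property table has a header but no rows")

    set_map = {"1": "training", "2": "test", "3": "external"}
    records = []
    for i, row in df.iterrows():
        raw = str(row["logbb"]).strip()
        try:
            logbb = float(raw)
        except ValueError:
            raise FormatError(
                f"row {i + 2}: non-numeric logbb value {raw!r} "
                f"for compound {row['id']!r}"
            ) from None
        label = str(row["set"]).strip().lower()
        label = set_map.get(label, label)
        records.append(
            PropertyRecord(
                compound_id=str(row["id"]).strip(),
                name=str(row["name"]).strip(),
                logbb=logbb,
                set_label=label,
                source_ref=str(row["ref"]).strip() if "ref" in df.columns else "",
            )
        )
    return records


def _select(records: Sequence[PropertyRecord], which: str) -> np.ndarray:
    if which == "all":
        vals = [r.logbb for r in records]
    else:
        if which not in SET_LABELS:
            raise ValueError(f"unknown set selector {which!r}")
        vals = [r.logbb for r in records if r.set_label == which]
    return np.asarray(vals, dtype=float)


def summarize_set(records: Sequence[PropertyRecord], which: str = "all") -> SetSummary:
    """Summary statistics and normality diagnostics for one subset.

    ``which`` is ``"training"``, ``"test"``, ``"external"`` or ``"all"``.
    The mean CI is the standard t-interval; the standard deviation uses
    the n-1 denominator.  Goodness-of-fit statistics are computed against
    a normal distribution with the subset's own mean and standard
    deviation: KS on the fitted CDF, Anderson-Darling A-squared, and a
    chi-squared test on Sturges-rule equal-width bins (degrees of freedom
    reduced by the two estimated parameters).
    """
    x = _select(records, which)
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 records in {which!r} subset, got {n}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    sem = sd / math.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    ks = stats.kstest(x, "norm", args=(mean, sd))
    ad = stats.anderson(x, dist="norm", method="interpolate")

    # Chi-squared GOF on Sturges-count equal-probability bins (stable in
    # the tails, unlike equal-width bins); df = bins - 1 - 2 estimated
    # parameters.
    k = int(np.ceil(np.log2(n) + 1))
    edges = stats.norm.ppf(np.linspace(0, 1, k + 1), mean, sd)
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(x, bins=edges)
    expected = np.full(k, n / k)
    cs = float(np.sum((observed - expected) ** 2 / expected))
    cs_df = max(1, k - 3)
    cs_p = float(stats.chi2.sf(cs, cs_df))

    jb = float(stats.jarque_bera(x).statistic)
    return SetSummary(
        n=n,
        mean=mean,
        mean_ci=(mean - tcrit * sem, mean + tcrit * sem),
        stdev=sd,
        min=float(x.min()),
        max=float(x.max()),
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        ad_stat=float(ad.statistic),
        cs_stat=cs,
        cs_p=cs_p,
        jb_stat=jb,
    )


def _relabel(records: Iterable[PropertyRecord], label: str) -> list[PropertyRecord]:
    return [
        PropertyRecord(r.compound_id, r.name, r.logbb, label, r.source_ref)
        for r in records
    ]


def random_split(
    records: Sequence[PropertyRecord],
    train_fraction: float = 2 / 3,
    seed: int = 0,
    require_normal: bool = False,
    alpha: float = 0.05,
    max_redraws: int = 1000,
) -> tuple[list[PropertyRecord], list[PropertyRecord]]:
    """Randomly partition records into training and test subsets.

    Sizes are ``round(n * train_fraction)`` and the remainder; the
    partition is deterministic for a fixed ``seed``.  With
    ``require_normal=True`` the draw is repeated (up to ``max_redraws``
    times) until both subsets pass a KS normality check at ``alpha``,
    emulating a randomization constrained to preserve normality of the
    property in both subsets.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(records)
    n_train = round(n * train_fraction)
    if n_train < 2 or n - n_train < 2:
        raise ValueError(f"n={n} too small to split at fraction {train_fraction}")
    rng = np.random.default_rng(seed)
    for _ in range(max_redraws):
        perm = rng.permutation(n)
        train = [records[i] for i in sorted(perm[:n_train])]
        test = [records[i] for i in sorted(perm[n_train:])]
        train = _relabel(train, "training")
        test = _relabel(test, "test")
        if not require_normal:
            return train, test
        ok = True
        for subset in (train, test):
            x = np.array([r.logbb for r in subset])
            m, s = x.mean(), x.std(ddof=1)
            if stats.kstest(x, "norm", args=(m, s)).pvalue < alpha:
                ok = False
                break
        if ok:
            return train, test
    raise RuntimeError(
        f"no normality-preserving split found in {max_redraws} redraws"
    )
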