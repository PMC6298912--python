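"""Two-group comparisons of US and CEUS parameters.

The study design compares a treated arm with controls independently at
each timepoint, parameter by parameter, with a two-tailed two-sample
t-test assuming unequal variances (Welch's test).  Because published
results are given as mean +/- SD per group, the test is implemented
directly from summary statistics; a sample-level entry point delegates to
it, so the two routes agree exactly.

No multiple-testing correction is applied by default, mirroring the
per-cell alpha = 0.05 design; an optional Benjamini-Hochberg switch is
provided for reuse in larger parameter panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarise",
    "welch_from_summary",
    "welch_from_samples",
    "compare_study",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard deviation (ddof=1) and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a group needs at least 2 observations")
        if not (self.sd >= 0) or not np.isfinite(self.sd) or not np.isfinite(self.mean):
            raise ValueError("mean and sd must be finite, sd non-negative")


@dataclass(frozen=True)
class ComparisonResult:
    """Welch test outcome: t statistic, degrees of freedom, two-tailed p."""

    t_stat: float
    df: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def summarise(x: Sequence[float]) -> GroupSummary:
    """Summary statistics (mean, sample sd, n) of one group."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D sample of at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample values must be finite")
    return GroupSummary(mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
                        n=int(arr.size))


def welch_from_summary(
    g1: GroupSummary, g2: GroupSummary, alpha: float = ALPHA
) -> ComparisonResult:
    """Welch's unequal-variance t-test from group summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with Welch-Satterthwaite
    degrees of freedom and a two-tailed p from the central t distribution.
    """
    v1 = g1.sd ** 2 / g1.n
    v2 = g2.sd ** 2 / g2.n
    se2 = v1 + v2
    if se2 == 0.0:
        raise ValueError("both groups have zero variance; the test is degenerate")
    t_stat = (g1.mean - g2.mean) / math.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    p = float(min(2.0 * t_dist.sf(abs(t_stat), df), 1.0))
    p = max(p, np.nextafter(0.0, 1.0))
    return ComparisonResult(t_stat=t_stat, df=df, p_value=p,
                            significant=p < alpha)


def welch_from_samples(
    x: Sequence[float], y: Sequence[float], alpha: float = ALPHA
) -> ComparisonResult:
    """Welch's t-test from raw samples; delegates to the summary route."""
    return welch_from_summary(summarise(x), summarise(y), alpha=alpha)


def compare_study(
    study: pd.DataFrame,
    parameters: Sequence[str] | None = None,
    arms: Sequence[str] | None = None,
    alpha: float = ALPHA,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-parameter, per-timepoint two-arm comparison of a study table.

    Parameters
    ----------
    study:
        Long-format table with ``arm`` and ``timepoint`` columns plus one
        numeric column per measured parameter.
    parameters:
        Columns to compare; defaults to every numeric column that is not
        a ground-truth (``true_``-prefixed) or identifier column.
    arms:
        The two arm labels, ``(treated, reference)``; defaults to the
        first two labels in the table, in order of appearance.  The t
        statistic is signed treated minus reference.
    adjust:
        ``None`` (default, per-cell alpha) or ``"bh"`` for a
        Benjamini-Hochberg adjustment across all cells.

    Returns
    -------
    A tidy frame with one row per parameter x timepoint carrying group
    summaries, ``t_stat``, ``df``, ``p_value`` and ``significant``.  A
    timepoint missing one arm (or with fewer than 2 animals in it) yields
    a row of NaNs rather than an error.
    """
    if "arm" not in study.columns or "timepoint" not in study.columns:
        raise ValueError("study table needs 'arm' and 'timepoint' columns")
    if arms is None:
        labels = list(pd.unique(study["arm"]))
        if len(labels) < 2:
            raise ValueError("study table must contain two arms")
        arms = tuple(labels[:2])
    a1, a2 = arms
    if parameters is None:
        skip = {"arm", "timepoint", "animal_id"}
        parameters = [c for c in study.columns
                      if c not in skip and not c.startswith("true_")
                      and pd.api.types.is_numeric_dtype(study[c])]

    timepoints = list(pd.unique(study["timepoint"]))
    rows = []
    for par in parameters:
        for tp in timepoints:
            sub = study[study["timepoint"] == tp]
            x = sub.loc[sub["arm"] == a1, par].dropna().to_numpy()
            y = sub.loc[sub["arm"] == a2, par].dropna().to_numpy()
            row = {
                "parameter": par, "timepoint": tp,
                f"mean_{a1}": np.nan, f"sd_{a1}": np.nan, f"n_{a1}": x.size,
                f"mean_{a2}": np.nan, f"sd_{a2}": np.nan, f"n_{a2}": y.size,
                "t_stat": np.nan, "df": np.nan, "p_value": np.nan,
                "significant": pd.NA,
            }
            if x.size >= 2:
                row[f"mean_{a1}"], row[f"sd_{a1}"] = x.mean(), x.std(ddof=1)
            if y.size >= 2:
                row[f"mean_{a2}"], row[f"sd_{a2}"] = y.mean(), y.std(ddof=1)
            if x.size >= 2 and y.size >= 2:
                try:
                    res = welch_from_samples(x, y, alpha=alpha)
                except ValueError:
                    pass  # degenerate cell stays NaN
                else:
                    row.update(t_stat=res.t_stat, df=res.df,
                               p_value=res.p_value, significant=res.significant)
            rows.append(row)
    out = pd.DataFrame(rows)

    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        ok = out["p_value"].notna()
        rej, q, _, _ = multipletests(out.loc[ok, "p_value"].to_numpy(),
                                     alpha=alpha, method="fdr_bh")
        out.loc[ok, "p_adjusted"] = q
        out.loc[ok, "significant"] = rej
    elif adjust is not None:
        raise ValueError("adjust must be None or 'bh'")
    return out
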