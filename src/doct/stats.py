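"""Group comparisons and time-course summaries of spheroid read-outs.

Small treatment groups (n = 5 per condition is typical here) call for an
exact Mann-Whitney U test: for group sizes up to 8 the two-sided p-value
is computed by full enumeration of all C(n1+n2, n1) assignments of the
pooled mid-ranks, counting arrangements whose U deviates from its null
mean n1*n2/2 at least as much as the observed one.  Larger groups fall
back to the normal approximation (tie-corrected, continuity-corrected).
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_GROUP_SIZE = 8


def _u_statistic_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def mannwhitney_exact_p(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumeration (ties via mid-ranks)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks under ties
    u_obs = _u_statistic_from_ranks(ranks[:n1].sum(), n1)
    center = n1 * n2 / 2.0
    dev_obs = abs(u_obs - center)
    hits = 0
    for subset in combinations(range(n1 + n2), n1):
        u = _u_statistic_from_ranks(sum(ranks[i] for i in subset), n1)
        if abs(u - center) >= dev_obs - 1e-12:
            hits += 1
    return hits / comb(n1 + n2, n1)


def compare_groups(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value between two groups of scalars.

    Exact enumeration when both groups have <= 8 observations, otherwise
    the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("group values must be finite")
    if max(len(a), len(b)) <= EXACT_MAX_GROUP_SIZE:
        return mannwhitney_exact_p(a, b)
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )


def time_course_table(
    records: pd.DataFrame,
    metrics: Optional[Iterable[str]] = None,
    exclude: Optional[Sequence[tuple]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize per-spheroid read-outs over a (condition, day) design.

    Parameters
    ----------
    records : DataFrame
        One row per measured spheroid with columns ``condition``, ``day``,
        ``replicate`` and one column per metric (volume, mean LIV, ...).
    metrics : iterable of str, optional
        Metric columns to summarize; defaults to every non-design column.
    exclude : sequence of (condition, day, replicate), optional
        Outlier exclusions; flagged rows are dropped from the statistics
        and n is decremented accordingly.

    Returns
    -------
    summary : DataFrame
        Per (metric, condition, day): mean, sd (n-1 divisor; NaN for a
        single replicate), n and the number of excluded replicates.
        Design cells with no remaining replicate are simply absent.
    pairwise : DataFrame
        Two-sided Mann-Whitney p-values between consecutive days within
        each condition and metric (NaN where a group has < 2 values).
    """
    required = {"condition", "day", "replicate"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    df = records.copy()
    if metrics is None:
        metrics = [c for c in df.columns if c not in required]
    metrics = list(metrics)
    excluded = pd.Series(False, index=df.index)
    if exclude:
        for cond, day, rep in exclude:
            excluded |= (
                (df["condition"] == cond) & (df["day"] == day) & (df["replicate"] == rep)
            )
    df["excluded"] = excluded

    rows = []
    for (cond, day), cell in df.groupby(["condition", "day"], sort=True):
        kept = cell.loc[~cell["excluded"]]
        for metric in metrics:
            values = kept[metric].dropna()
            if len(values) == 0:
                continue
            rows.append(
                {
                    "metric": metric,
                    "condition": cond,
                    "day": day,
                    "mean": values.mean(),
                    "sd": values.std(ddof=1) if len(values) > 1 else np.nan,
                    "n": len(values),
                    "n_excluded": int(cell["excluded"].sum()),
                }
            )
    summary = pd.DataFrame(rows)

    pair_rows = []
    kept_df = df.loc[~df["excluded"]]
    for cond, sub in kept_df.groupby("condition", sort=True):
        days = sorted(sub["day"].unique())
        for d0, d1 in zip(days[:-1], days[1:]):
            for metric in metrics:
                g0 = sub.loc[sub["day"] == d0, metric].dropna().to_numpy()
                g1 = sub.loc[sub["day"] == d1, metric].dropna().to_numpy()
                p = compare_groups(g0, g1) if min(len(g0), len(g1)) >= 2 else np.nan
                pair_rows.append(
                    {
                        "metric": metric,
                        "condition": cond,
                        "day_from": d0,
                        "day_to": d1,
                        "p_value": p,
                    }
                )
    pairwise = pd.DataFrame(pair_rows)
    return summary, pairwise
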