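"""Nonparametric algorithm comparison: Wilcoxon rank-sum and Friedman ranks.

Two bookkeeping conventions from the benchmarking literature are
implemented on top of the tests themselves:

* win/tie/loss — per problem, a *tie* when the two-sided rank-sum test
  fails at the 5% level, otherwise decided by comparing means in the
  metric's direction;
* Friedman mean ranks — within each problem the algorithms are ranked
  (1 = best, mid-rank ties), and the per-algorithm rank means induce the
  overall ordering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "wilcoxon_rank_sum",
    "win_tie_loss",
    "friedman_mean_ranks",
]

_EXACT_MAX_N = 12


def wilcoxon_rank_sum(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum p-value.

    Uses the exact null distribution when the pooled size is at most 12
    and there are no ties, and the tie-corrected normal approximation
    otherwise.  Degenerate input — all pooled values identical, so the
    test carries no information — returns NaN.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float("nan")
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def win_tie_loss(
    reference_runs: dict[str, np.ndarray],
    competitor_runs: dict[str, np.ndarray],
    alpha: float = 0.05,
    direction: str = "lower",
) -> dict[str, int | dict]:
    """Per-problem significance bookkeeping for two algorithms.

    ``reference_runs`` / ``competitor_runs`` map problem name to the
    per-run metric samples of each algorithm.  A problem is a *tie* when
    the rank-sum p-value is >= ``alpha`` (or NaN); otherwise the reference
    *wins* if its mean is better in ``direction`` (``"lower"`` for
    fitness, ``"higher"`` for accuracy) and *loses* otherwise.
    """
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    if set(reference_runs) != set(competitor_runs):
        raise ValueError("the two run dictionaries must cover the same problems")
    result = {"win": 0, "tie": 0, "loss": 0, "per_problem": {}}
    for problem in reference_runs:
        ref = np.asarray(reference_runs[problem], dtype=float)
        comp = np.asarray(competitor_runs[problem], dtype=float)
        p = wilcoxon_rank_sum(ref, comp)
        if np.isnan(p) or p >= alpha:
            verdict = "tie"
        else:
            better = ref.mean() < comp.mean() if direction == "lower" else ref.mean() > comp.mean()
            verdict = "win" if better else "loss"
        result[verdict] += 1
        result["per_problem"][problem] = {"p_value": p, "verdict": verdict}
    return result


def friedman_mean_ranks(
    table: pd.DataFrame | np.ndarray,
    lower_is_better: bool = True,
) -> pd.DataFrame:
    """Friedman mean ranks over a problems x algorithms metric table.

    Within each row the algorithms are ranked 1 = best with mid-rank tie
    handling; the returned frame holds each algorithm's mean rank and the
    induced overall ranking (1 = lowest mean rank).  The Friedman
    chi-square statistic and its p-value are attached as ``frame.attrs``.
    """
    df = pd.DataFrame(table)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 algorithms to rank")
    values = df.to_numpy(dtype=float)
    if not lower_is_better:
        values = -values
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    mean_ranks = ranks.mean(axis=0)
    order = stats.rankdata(mean_ranks, method="min")
    out = pd.DataFrame(
        {"mean_rank": mean_ranks, "overall_rank": order.astype(int)},
        index=df.columns,
    )
    if df.shape[0] >= 2 and df.shape[1] >= 3:  # chi-square needs >= 3 algorithms
        stat, p = stats.friedmanchisquare(*[values[:, j] for j in range(values.shape[1])])
        out.attrs["friedman_statistic"] = float(stat)
        out.attrs["friedman_pvalue"] = float(p)
    return out
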