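"""Friedman and Nemenyi statistics for comparing methods across datasets.

Given an N x k score table (N datasets, k methods), each row is ranked
(rank 1 = best, average ranks on ties) and the Friedman statistic

    chi2_F = 12 N / (k (k+1)) * [ sum_j R_j^2 - k (k+1)^2 / 4 ]

tests the null that all methods are equivalent, where R_j is the mean rank
of method j.  Because chi2_F is conservative, the F-distributed refinement

    F_F = (N-1) chi2_F / (N (k-1) - chi2_F)

with (k-1, (k-1)(N-1)) degrees of freedom is used for the decision.  After a
rejection, the Nemenyi post-hoc test declares two methods significantly
different when their mean ranks differ by more than the critical difference

    CD = q_alpha * sqrt(k (k+1) / (6 N))

with q_alpha the studentized-range quantile at infinite degrees of freedom
divided by sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RankMatrix",
    "FriedmanResult",
    "rank_methods",
    "friedman_chi2",
    "friedman_ff",
    "f_critical",
    "nemenyi_qalpha",
    "nemenyi_cd",
    "compare_methods",
]


@dataclass
class RankMatrix:
    """Within-dataset ranks of k methods over N datasets."""

    ranks: np.ndarray  # (N, k), rank 1 = best, ties averaged
    mean_ranks: np.ndarray  # length k
    methods: list[str]

    @property
    def N(self) -> int:
        return self.ranks.shape[0]

    @property
    def k(self) -> int:
        return self.ranks.shape[1]


def rank_methods(score_table, higher_is_better: bool = True) -> RankMatrix:
    """Rank methods within each dataset row; ties get average ranks."""
    if isinstance(score_table, pd.DataFrame):
        methods = [str(c) for c in score_table.columns]
        values = score_table.to_numpy(dtype=float)
    else:
        values = np.asarray(score_table, dtype=float)
        methods = [f"m{j}" for j in range(values.shape[1])]
    if values.ndim != 2:
        raise ValueError("score table must be 2-D (datasets x methods)")
    if not np.all(np.isfinite(values)):
        raise ValueError("score table has missing or non-finite cells")
    signed = -values if higher_is_better else values
    ranks = sps.rankdata(signed, axis=1)
    return RankMatrix(ranks=ranks, mean_ranks=ranks.mean(axis=0), methods=methods)


def friedman_chi2(rank_matrix: RankMatrix) -> float:
    """chi2_F = 12N/(k(k+1)) [sum R_j^2 - k(k+1)^2/4]."""
    N, k = rank_matrix.N, rank_matrix.k
    if N < 2 or k < 2:
        raise ValueError("need at least 2 datasets and 2 methods")
    R = rank_matrix.mean_ranks
    return float(12.0 * N / (k * (k + 1)) * (np.sum(R**2) - k * (k + 1) ** 2 / 4.0))


def friedman_ff(chi2_f: float, N: int, k: int) -> float:
    """F-distributed refinement F_F = (N-1) chi2_F / (N(k-1) - chi2_F)."""
    denom = N * (k - 1) - chi2_f
    if denom <= 0:
        raise ValueError(
            "chi2_F equals its maximum N(k-1) (perfect agreement); F_F is infinite"
        )
    return float((N - 1) * chi2_f / denom)


def f_critical(alpha: float, k: int, N: int) -> float:
    """Upper-alpha quantile of F with (k-1, (k-1)(N-1)) degrees of freedom."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df1, df2 = k - 1, (k - 1) * (N - 1)
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom")
    return float(sps.f.ppf(1 - alpha, df1, df2))


def nemenyi_qalpha(alpha: float, k: int) -> float:
    """q_alpha = studentized-range quantile (k groups, df=inf) / sqrt(2)."""
    if not 0 < alpha < 1 or k < 2:
        raise ValueError("need 0 < alpha < 1 and k >= 2")
    return float(sps.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2.0))


def nemenyi_cd(q_alpha: float, k: int, N: int) -> float:
    """Critical difference CD = q_alpha sqrt(k(k+1)/(6N))."""
    if q_alpha <= 0 or k < 2 or N < 1:
        raise ValueError("arguments must be positive (k >= 2)")
    return float(q_alpha * np.sqrt(k * (k + 1) / (6.0 * N)))


@dataclass
class FriedmanResult:
    chi2_f: float
    ff: float
    df1: int
    df2: int
    critical_value: float
    reject: bool
    cd: float
    mean_ranks: pd.Series
    significant_vs_control: pd.Series | None

    def to_dict(self) -> dict:
        out = {
            "chi2_f": self.chi2_f,
            "ff": self.ff,
            "df1": self.df1,
            "df2": self.df2,
            "critical_value": self.critical_value,
            "reject": self.reject,
            "cd": self.cd,
            "mean_ranks": self.mean_ranks.to_dict(),
        }
        if self.significant_vs_control is not None:
            out["significant_vs_control"] = {
                k: bool(v) for k, v in self.significant_vs_control.items()
            }
        return out


def compare_methods(
    score_table,
    higher_is_better: bool = True,
    alpha: float = 0.05,
    q_alpha: float | None = None,
    control: str | None = None,
) -> FriedmanResult:
    """Full comparison: ranks, chi2_F, F_F, F critical value, Nemenyi CD.

    ``control`` names the method whose mean-rank gaps are flagged against
    the CD (defaults to the best-ranked method).
    """
    rm = rank_methods(score_table, higher_is_better=higher_is_better)
    chi2 = friedman_chi2(rm)
    try:
        ff = friedman_ff(chi2, rm.N, rm.k)
    except ValueError:
        ff = float("inf")
    crit = f_critical(alpha, rm.k, rm.N)
    q = nemenyi_qalpha(alpha, rm.k) if q_alpha is None else q_alpha
    cd = nemenyi_cd(q, rm.k, rm.N)
    mean_ranks = pd.Series(rm.mean_ranks, index=rm.methods)
    if control is None:
        control = mean_ranks.idxmin()
    gaps = (mean_ranks - mean_ranks[control]).drop(index=control)
    return FriedmanResult(
        chi2_f=chi2,
        ff=ff,
        df1=rm.k - 1,
        df2=(rm.k - 1) * (rm.N - 1),
        critical_value=crit,
        reject=bool(ff > crit),
        cd=cd,
        mean_ranks=mean_ranks,
        significant_vs_control=gaps > cd,
    )
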