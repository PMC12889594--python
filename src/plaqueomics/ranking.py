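"""Order-statistics consensus ranking across independent studies.

Each study contributes a ranking of its own protein universe. For a
protein seen in ``N`` studies with normalized ranks ``r_1 <= ... <= r_N``
(rank divided by universe size, so each r is in (0, 1]), the consensus
statistic is the joint probability

    Q = P(U_(1) <= r_1, ..., U_(N) <= r_N)

that all N order statistics of N independent Uniform(0,1) draws fall
below the observed normalized ranks. A small Q means the protein is
consistently top-ranked across studies; the consensus list orders
proteins by Q ascending. Q is used purely ordinally (no null
calibration is attached).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import factorial
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DatasetRanking",
    "ranking_from_scores",
    "read_ranking_tsv",
    "normalize_ranks",
    "order_statistic_q",
    "aggregate_rankings",
]


@dataclass
class DatasetRanking:
    """One study's protein ranking (best first, average ranks for ties)."""

    dataset_id: str
    ranks: pd.Series  # protein id -> rank in 1..M (ties share the average rank)
    universe_size: int

    def __post_init__(self) -> None:
        if self.ranks.index.duplicated().any():
            raise ValueError(f"duplicate protein ids in ranking {self.dataset_id!r}")
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        r = self.ranks.to_numpy(dtype=float)
        if (r < 1).any() or (r > self.universe_size).any():
            raise ValueError("ranks must lie in 1..universe_size")


def ranking_from_scores(
    dataset_id: str, scores: pd.Series, ascending: bool = True
) -> DatasetRanking:
    """Build a ranking from per-protein scores (default: smaller is better)."""
    if scores.index.duplicated().any():
        raise ValueError("duplicate protein ids in scores")
    vals = scores.to_numpy(dtype=float)
    ranks = rankdata(vals if ascending else -vals, method="average")
    return DatasetRanking(dataset_id, pd.Series(ranks, index=scores.index), len(scores))


def read_ranking_tsv(path, dataset_id: str | None = None) -> DatasetRanking:
    """Read a per-study TSV: either ``protein_id<TAB>rank`` or
    ``protein_id<TAB>score[<TAB>direction]`` (scores converted to ranks,
    ascending unless direction says ``desc``)."""
    df = pd.read_csv(path, sep="\t")
    dataset_id = dataset_id or str(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "rank" in cols:
        s = pd.Series(df["rank"].to_numpy(float), index=df["protein_id"])
        return DatasetRanking(dataset_id, s, int(s.max()))
    ascending = True
    if "direction" in cols and str(df["direction"].iloc[0]).lower().startswith("desc"):
        ascending = False
    return ranking_from_scores(
        dataset_id, pd.Series(df["score"].to_numpy(float), index=df["protein_id"]), ascending
    )


def normalize_ranks(ranking: DatasetRanking) -> pd.Series:
    """Normalized ranks r = rank / M, each in (0, 1]."""
    return ranking.ranks / float(ranking.universe_size)


def order_statistic_q(r_sorted: Sequence[float]) -> float:
    """Joint uniform order-statistic probability Q for ascending ranks.

    Evaluates ``Q = N! * V_N`` with the recursion

        V_0 = 1,
        V_k = sum_{i=1..k} (-1)^(i-1) * V_{k-i} / i! * r_{N-k+1}^i,

    carried out in exact rational arithmetic so the alternating sum is
    stable for any N up to ~20; the result is clamped to (0, 1].
    """
    r = [float(x) for x in r_sorted]
    n = len(r)
    if n == 0:
        raise ValueError("need at least one rank")
    if any(not (0.0 < x <= 1.0) for x in r):
        raise ValueError("normalized ranks must lie in (0, 1]")
    if any(r[i] > r[i + 1] for i in range(n - 1)):
        raise ValueError("ranks must be sorted ascending")
    rf = [Fraction(x) for x in r]
    v = [Fraction(1)]
    for k in range(1, n + 1):
        term = Fraction(0)
        rk = rf[n - k]  # r_{N-k+1}, 1-indexed
        rk_pow = Fraction(1)
        for i in range(1, k + 1):
            rk_pow *= rk
            contrib = v[k - i] * rk_pow / factorial(i)
            term += contrib if i % 2 == 1 else -contrib
        v.append(term)
    q = float(factorial(n) * v[n])
    return min(1.0, max(q, np.nextafter(0.0, 1.0)))


def aggregate_rankings(
    rankings: Iterable[DatasetRanking],
    min_datasets: int = 3,
    missing_policy: str = "available",
) -> pd.DataFrame:
    """Combine per-study rankings into one consensus list ordered by Q.

    Parameters
    ----------
    rankings
        The per-study rankings.
    min_datasets
        Proteins present in fewer studies are reported as unrankable
        (``rankable`` False, Q of NaN). With a single input study the
        filter drops to 1 so the consensus reduces to that study.
    missing_policy
        ``"available"`` computes Q over the studies where the protein is
        present (N = number available); ``"worst"`` imputes r = 1 for
        each absent study so every protein uses N = number of studies.

    Returns
    -------
    DataFrame with columns ``protein_id, n_datasets, Q, consensus_rank,
    normalized_ranks, rankable``, ordered by Q ascending (ties broken by
    mean normalized rank, then protein id); unrankable proteins follow.
    """
    rankings = list(rankings)
    if not rankings:
        raise ValueError("need at least one ranking")
    if missing_policy not in {"available", "worst"}:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    min_datasets = min(min_datasets, len(rankings))

    norm = {rk.dataset_id: normalize_ranks(rk) for rk in rankings}
    universe = sorted(set().union(*(set(s.index) for s in norm.values())))

    rows = []
    for pid in universe:
        rs = [float(s.loc[pid]) for s in norm.values() if pid in s.index]
        n_avail = len(rs)
        if missing_policy == "worst":
            rs = rs + [1.0] * (len(rankings) - n_avail)
        rankable = n_avail >= min_datasets
        q = order_statistic_q(sorted(rs)) if rankable else np.nan
        rows.append(
            {
                "protein_id": pid,
                "n_datasets": n_avail,
                "Q": q,
                "mean_r": float(np.mean(rs)),
                "normalized_ranks": ";".join(f"{x:.6g}" for x in sorted(rs)),
                "rankable": rankable,
            }
        )
    df = pd.DataFrame(rows)
    if df["rankable"].sum() == 0:
        import warnings

        warnings.warn("no protein present in enough datasets; consensus is empty")
    df = df.sort_values(
        by=["rankable", "Q", "mean_r", "protein_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ranks = np.full(len(df), np.nan)
    n_rankable = int(df["rankable"].sum())
    ranks[:n_rankable] = np.arange(1, n_rankable + 1)
    df["consensus_rank"] = ranks
    return df.drop(columns=["mean_r"])
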