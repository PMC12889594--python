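"""Temporal classification of plaque-enriched proteins across ages.

Per-protein mean plaque abundance at each age is baseline-normalized by
subtracting the earliest-age mean (log scale), giving relative fold
changes Δ(age). Proteins whose 8- and 14-month deltas point in opposite
directions (beyond a small tolerance) are excluded, and the remainder
fall into three trajectory clusters with a deterministic threshold rule
on the deltas:

* ``decline``        — Δ(last) <= -tau
* ``late``           — Δ(last) >= tau and Δ(mid) < tau
* ``early_constant`` — everything else

An optional agglomerative mode (average linkage on the delta vectors,
k = 3) is available for exploration but is not the default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .matrix import IntensityMatrix, PLAQUE

__all__ = [
    "baseline_normalize",
    "direction_filter",
    "assign_clusters",
    "classify_trajectories",
    "hierarchical_clusters",
]

EARLY = "early_constant"
LATE = "late"
DECLINE = "decline"


def baseline_normalize(
    plaque_means: pd.DataFrame, baseline_age=None
) -> pd.DataFrame:
    """Subtract the baseline-age mean from every age column.

    ``plaque_means`` is proteins x ages (mean log2 plaque abundance);
    the baseline defaults to the smallest age. Proteins missing any age
    mean are excluded (``excluded`` True with reason) since their
    trajectory is undefined.
    """
    ages = sorted(plaque_means.columns, key=float)
    if baseline_age is None:
        baseline_age = ages[0]
    if baseline_age not in plaque_means.columns:
        raise ValueError(f"baseline age {baseline_age!r} absent from columns")
    out = plaque_means[ages].copy()
    complete = out.notna().all(axis=1)
    deltas = out.sub(out[baseline_age], axis=0)
    deltas["excluded"] = ~complete
    deltas["reason"] = np.where(complete, "", "missing age stratum")
    return deltas


def direction_filter(deltas: pd.DataFrame, tol: float = 0.1) -> pd.DataFrame:
    """Exclude proteins with opposite fold-change directions at the two
    post-baseline ages, ignoring sub-tolerance deltas (|Δ| <= tol)."""
    ages = [c for c in deltas.columns if c not in ("excluded", "reason")]
    if len(ages) < 3:
        return deltas  # nothing to compare
    mid, last = ages[1], ages[-1]
    out = deltas.copy()
    d8 = out[mid].to_numpy(float)
    d14 = out[last].to_numpy(float)
    with np.errstate(invalid="ignore"):
        flip = (np.sign(d8) != np.sign(d14)) & (np.abs(d8) > tol) & (np.abs(d14) > tol)
    flip &= ~out["excluded"].to_numpy(bool)
    out.loc[flip, "excluded"] = True
    out.loc[flip, "reason"] = "opposite fold-change directions"
    return out


def assign_clusters(deltas: pd.DataFrame, tau: float = 0.5) -> pd.DataFrame:
    """Assign each non-excluded protein to one trajectory cluster."""
    ages = [c for c in deltas.columns if c not in ("excluded", "reason")]
    mid = ages[1] if len(ages) >= 3 else ages[-1]
    last = ages[-1]
    out = deltas.copy()
    cluster = []
    for pid, row in out.iterrows():
        if bool(row["excluded"]):
            cluster.append(None)
            continue
        d_mid, d_last = float(row[mid]), float(row[last])
        if d_last <= -tau:
            cluster.append(DECLINE)
        elif d_last >= tau and d_mid < tau:
            cluster.append(LATE)
        else:
            cluster.append(EARLY)
    out["cluster"] = cluster
    return out


def classify_trajectories(
    m: IntensityMatrix,
    dap_ids,
    baseline_age=None,
    tol: float = 0.1,
    tau: float = 0.5,
) -> pd.DataFrame:
    """Full temporal stage on the plaque samples of the given DAPs.

    Computes per-age mean log2 plaque abundance, baseline-normalizes,
    applies the direction filter, and assigns clusters. Returns a
    proteins-indexed DataFrame with the per-age deltas plus ``excluded,
    reason, cluster``.
    """
    meta = m.meta()
    plaque_cols = meta.index[meta["region"] == PLAQUE]
    ages = sorted(meta["age_months"].unique(), key=float)
    keep = [p for p in m.values.index if p in set(dap_ids)]
    means = pd.DataFrame(index=keep, columns=ages, dtype=float)
    for age in ages:
        cols = [s for s in plaque_cols if meta.loc[s, "age_months"] == age]
        means[age] = m.values.loc[keep, cols].mean(axis=1, skipna=True)
    deltas = baseline_normalize(means, baseline_age=baseline_age)
    deltas = direction_filter(deltas, tol=tol)
    return assign_clusters(deltas, tau=tau)


def hierarchical_clusters(deltas: pd.DataFrame, k: int = 3) -> pd.Series:
    """Exploratory alternative: average-linkage clustering of the delta
    vectors into k groups (labels are arbitrary integers)."""
    ages = [c for c in deltas.columns if c not in ("excluded", "reason", "cluster")]
    sub = deltas.loc[~deltas["excluded"].astype(bool), ages]
    if len(sub) < k:
        raise ValueError("fewer proteins than clusters")
    z = linkage(sub.to_numpy(float), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=sub.index, name="hclust")
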