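"""Detection-aware differential abundance for paired plaque proteomics.

The five-step procedure applied independently to each model-by-age
stratum:

1. **Detection G test** — per protein, a likelihood-ratio test on the
   2x2 table of detected/missing counts in plaque vs. control samples
   (detection count as a proxy for abundance under left-censoring).
2. **Conditional equalizing imputation** — only when the G test is
   significant, missing cells in the group with fewer detections are
   imputed with the *sample-specific minimum* observed intensity (the
   per-sample detection floor) until detection counts are equal; the
   better-detected group is never modified and not all missing values
   are filled.
3. **Moderated paired t-test** — per-protein paired log2 differences
   tested with an empirical-Bayes variance shrunk toward a prior
   ``(d0, s2_0)`` fitted across proteins by the scaled-F method of
   moments on log sample variances; with ``d0 = 0`` this is exactly the
   classical paired t-test.
4. **Benjamini–Hochberg FDR** across tested proteins within the stratum.
5. **log2FC-z thresholding** — fold changes standardized across all
   tested proteins of the comparison; a protein is a DAP when
   ``q < 0.05`` and ``|z|`` exceeds the species threshold (2.5 mouse,
   2.0 human).

A separate screen ranks proteins by their Pearson correlation with the
amyloid-beta tracer across plaque samples.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .matrix import IntensityMatrix, PLAQUE, NONPLAQUE

__all__ = [
    "g_test",
    "equalizing_impute",
    "moderated_paired_ttest",
    "fit_variance_prior",
    "bh_fdr",
    "log2fc_zscores",
    "call_daps",
    "differential_analysis",
    "tracer_correlation_screen",
]


# ----------------------------------------------------------------------
# Step 1: detection G test
# ----------------------------------------------------------------------


def g_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Likelihood-ratio (G) test of equal detection proportions.

    The 2x2 table is detected/missing by group; ``G = 2 * sum O*ln(O/E)``
    with expected counts from the marginals, zero-count cells
    contributing zero, and the p-value from chi-square with 1 df.
    Degenerate margins (all detected in both groups, or all missing in
    both) give ``G = 0, p = 1`` by convention.

    Returns
    -------
    (G, p)
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2 and n1 >= 1 and n2 >= 1):
        raise ValueError("invalid detection table")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    col = obs.sum(axis=0)
    if col[0] == 0 or col[1] == 0:  # same detection status everywhere
        return 0.0, 1.0
    row = obs.sum(axis=1)
    total = obs.sum()
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = float(2.0 * terms.sum())
    g = max(g, 0.0)
    return g, float(stats.chi2.sf(g, df=1))


# ----------------------------------------------------------------------
# Step 2: conditional equalizing imputation
# ----------------------------------------------------------------------


def equalizing_impute(
    m: IntensityMatrix,
    protein: str,
    group1: Sequence[str],
    group2: Sequence[str],
    g_p: float,
    alpha: float = 0.05,
) -> tuple[pd.Series, list[str]]:
    """Impute a protein's missing cells to equalize detection counts.

    No-op when ``g_p >= alpha``. Otherwise the group with fewer
    detections has its missing cells filled — each with that *sample's*
    minimum observed intensity across all proteins — in ascending
    sample-id order until the detection counts are equal or no missing
    cells remain. The better-detected group is never touched.

    Returns the protein's updated value series and the list of imputed
    sample ids.
    """
    if protein not in m.values.index:
        raise KeyError(f"protein {protein!r} absent")
    if set(group1) & set(group2):
        raise ValueError("groups must be disjoint")
    minima = m.values.min(axis=0, skipna=True)
    return _equalize_row(m.values.loc[protein], list(group1), list(group2), minima, g_p, alpha)


def _equalize_row(
    row: pd.Series,
    group1: list[str],
    group2: list[str],
    sample_minima: pd.Series,
    g_p: float,
    alpha: float,
) -> tuple[pd.Series, list[str]]:
    row = row.copy()
    if not (g_p < alpha):
        return row, []
    det1 = int(row[group1].notna().sum())
    det2 = int(row[group2].notna().sum())
    if det1 == det2:
        return row, []
    deficient, det_low, det_high = (
        (group1, det1, det2) if det1 < det2 else (group2, det2, det1)
    )
    imputed: list[str] = []
    for sid in sorted(deficient):
        if det_low >= det_high:
            break
        if pd.isna(row[sid]) and not pd.isna(sample_minima[sid]):
            row[sid] = float(sample_minima[sid])
            imputed.append(sid)
            det_low += 1
    return row, imputed


# ----------------------------------------------------------------------
# Step 3: moderated paired t-test
# ----------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F prior to sample variances.

    Models ``s2_g ~ s2_0 * F(d_g, d0)`` and estimates ``(d0, s2_0)``
    from the mean and excess variance of ``log s2_g`` (the classic
    empirical-Bayes fit used for variance moderation). Returns
    ``d0 = inf`` when the observed spread of log-variances is no larger
    than expected from chi-square sampling alone.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return 0.0, float(np.nan)
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1) - np.mean(polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s2_0 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s2_0 = math.exp(emean)
    return d0, s2_0


def moderated_paired_ttest(
    diffs: pd.DataFrame,
    d0: float | None = None,
    s2_0: float | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Empirical-Bayes moderated paired t-test per protein.

    Parameters
    ----------
    diffs
        Proteins-by-pairs matrix of paired log2 differences; NaN marks
        an incomplete pair, dropped per protein. Proteins with fewer
        than ``min_pairs`` complete pairs are reported untested.
    d0, s2_0
        Prior degrees of freedom and prior variance. Estimated across
        proteins when None; pass ``d0 = 0`` to force the classical
        paired t-test.

    Returns
    -------
    DataFrame indexed by protein with columns ``mean_diff, s2_g, d_g,
    n_pairs, s2_post, t_mod, df_total, p, tested, reason``; the fitted
    prior is stored in ``result.attrs['d0']`` / ``attrs['s2_0']``.
    """
    arr = diffs.to_numpy(dtype=float)
    n_obs = np.sum(np.isfinite(arr), axis=1)
    mean_diff = np.full(len(diffs), np.nan)
    s2_g = np.full(len(diffs), np.nan)
    tested = n_obs >= min_pairs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_diff[tested] = np.nanmean(arr[tested], axis=1)
        s2_g[tested] = np.nanvar(arr[tested], axis=1, ddof=1)
    d_g = np.where(tested, n_obs - 1.0, np.nan)

    if d0 is None or s2_0 is None:
        if tested.any() and np.all(s2_g[tested] == 0):
            warnings.warn("all per-protein variances are zero; falling back to "
                          "the classical paired t-test")
            fit_d0, fit_s2_0 = 0.0, 0.0
        else:
            fit_d0, fit_s2_0 = fit_variance_prior(s2_g, d_g)
        d0 = fit_d0 if d0 is None else d0
        s2_0 = fit_s2_0 if s2_0 is None else s2_0

    if math.isinf(d0):
        s2_post = np.full_like(s2_g, s2_0)
        df_total = np.full_like(s2_g, np.inf)
    else:
        s2_post = (d0 * s2_0 + d_g * s2_g) / (d0 + d_g) if d0 > 0 else s2_g
        df_total = d0 + d_g

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post / n_obs)
        t_mod = np.where(se > 0, mean_diff / np.where(se > 0, se, 1.0), np.nan)
    # zero posterior variance: infinite evidence unless the mean is zero too
    zero_se = tested & ~(se > 0)
    t_mod[zero_se & (mean_diff != 0)] = np.inf * np.sign(mean_diff[zero_se & (mean_diff != 0)])
    t_mod[zero_se & (mean_diff == 0)] = 0.0
    p = np.full(len(diffs), np.nan)
    finite_t = tested & np.isfinite(t_mod)
    p[finite_t] = 2.0 * stats.t.sf(np.abs(t_mod[finite_t]), df_total[finite_t])
    p[tested & np.isposinf(np.abs(t_mod))] = 0.0
    p = np.clip(p, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "s2_g": s2_g,
            "d_g": d_g,
            "n_pairs": n_obs,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "tested": tested,
            "reason": np.where(tested, "", f"fewer than {min_pairs} complete pairs"),
        },
        index=diffs.index,
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s2_0"] = float(s2_0)
    return out


# ----------------------------------------------------------------------
# Steps 4-5: BH FDR, log2FC-z, DAP call
# ----------------------------------------------------------------------


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN inputs yield NaN and are
    excluded from the number of tests."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def log2fc_zscores(log2fcs) -> np.ndarray:
    """Standardize fold changes across the tested proteins of one
    comparison (sample sd, ddof 1)."""
    x = np.asarray(log2fcs, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValueError("need at least two finite fold changes")
    sd = float(np.std(finite, ddof=1))
    if sd == 0:
        raise ValueError("degenerate comparison: zero fold-change spread")
    return (x - float(np.mean(finite))) / sd


def call_daps(
    records: pd.DataFrame, fdr_threshold: float = 0.05, z_threshold: float = 2.5
) -> pd.DataFrame:
    """Flag DAPs: ``q < fdr_threshold`` and ``|z| > z_threshold``.

    Untested proteins (NaN q or z) are never DAPs. Direction follows the
    sign of the fold change (positive = enriched in plaques).
    """
    out = records.copy()
    q = out["q"].to_numpy(float)
    z = out["z"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        out["is_dap"] = (q < fdr_threshold) & (np.abs(z) > z_threshold)
    out["is_dap"] = out["is_dap"].fillna(False).astype(bool)
    out["direction"] = np.where(
        out["log2fc"].to_numpy(float) >= 0, "up_in_plaque", "down_in_plaque"
    )
    return out


# ----------------------------------------------------------------------
# Full stage
# ----------------------------------------------------------------------


def differential_analysis(
    m: IntensityMatrix,
    fdr_threshold: float = 0.05,
    z_threshold: float = 2.5,
    g_alpha: float = 0.05,
    min_pairs: int = 3,
    d0: float | None = None,
    s2_0: float | None = None,
) -> pd.DataFrame:
    """Run the five-step DAP procedure on every model-by-age stratum.

    Returns one row per (protein, stratum): ``protein_id, model,
    age_months, log2fc, z, p, q, g_p, imputed_count, n_pairs, tested,
    reason, is_dap, direction``. Strata are analyzed separately and
    fold changes standardized within stratum.
    """
    frames = []
    for model, age in m.strata():
        sub = m.stratum(model, age)
        meta = sub.meta()
        plaque = sorted(meta.index[meta["region"] == PLAQUE])
        control = sorted(meta.index[meta["region"] == NONPLAQUE])
        pair_ids = sorted(meta["pair_id"].unique())
        plq_of = {meta.loc[s, "pair_id"]: s for s in plaque}
        ctl_of = {meta.loc[s, "pair_id"]: s for s in control}

        values = sub.values
        det = values.notna()
        k1 = det[plaque].sum(axis=1).to_numpy()
        k2 = det[control].sum(axis=1).to_numpy()
        n1, n2 = len(plaque), len(control)
        sample_minima = values.min(axis=0, skipna=True)

        g_p = np.empty(len(values))
        imputed_count = np.zeros(len(values), dtype=int)
        work = values.copy()
        for i, pid in enumerate(values.index):
            _, g_p[i] = g_test(int(k1[i]), n1, int(k2[i]), n2)
            if g_p[i] < g_alpha:
                row, imputed = _equalize_row(
                    values.loc[pid], plaque, control, sample_minima, g_p[i], g_alpha
                )
                if imputed:
                    work.loc[pid] = row
                    imputed_count[i] = len(imputed)

        diffs = pd.DataFrame(
            {pr: work[plq_of[pr]] - work[ctl_of[pr]] for pr in pair_ids},
            index=work.index,
        )
        test = moderated_paired_ttest(diffs, d0=d0, s2_0=s2_0, min_pairs=min_pairs)

        res = pd.DataFrame(
            {
                "protein_id": work.index,
                "model": model,
                "age_months": age,
                "log2fc": test["mean_diff"].to_numpy(),
                "p": test["p"].to_numpy(),
                "g_p": g_p,
                "imputed_count": imputed_count,
                "n_pairs": test["n_pairs"].to_numpy(),
                "tested": test["tested"].to_numpy(),
                "reason": test["reason"].to_numpy(),
            }
        )
        res["q"] = bh_fdr(np.where(res["tested"], res["p"], np.nan))
        z = np.full(len(res), np.nan)
        tested_mask = res["tested"].to_numpy()
        if tested_mask.sum() >= 2:
            z[tested_mask] = log2fc_zscores(res.loc[tested_mask, "log2fc"])
        res["z"] = z
        res = call_daps(res, fdr_threshold=fdr_threshold, z_threshold=z_threshold)
        res.attrs = {}
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    return out


# ----------------------------------------------------------------------
# Tracer correlation screen
# ----------------------------------------------------------------------


def tracer_correlation_screen(
    m: IntensityMatrix,
    tracer_id: str,
    r_threshold: float = 0.8,
    top_k: int = 20,
    plaque_only: bool = True,
    min_overlap: int = 6,
) -> pd.DataFrame:
    """Pearson correlation of every protein with the tracer profile.

    Computed across plaque samples pooled over ages (all samples when
    ``plaque_only`` is False), pairwise-complete. Proteins overlapping
    the tracer in fewer than ``min_overlap`` samples are skipped.

    Returns a DataFrame sorted by R descending with columns
    ``protein_id, r, n_obs, above_threshold, top_k`` (the tracer itself
    is excluded).
    """
    if tracer_id not in m.values.index:
        raise KeyError(f"tracer {tracer_id!r} not present")
    meta = m.meta()
    cols = list(meta.index[meta["region"] == PLAQUE]) if plaque_only else list(meta.index)
    tracer = m.values.loc[tracer_id, cols].to_numpy(float)
    rows = []
    for pid in m.values.index:
        if pid == tracer_id:
            continue
        x = m.values.loc[pid, cols].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(tracer)
        n = int(ok.sum())
        if n < min_overlap:
            rows.append({"protein_id": pid, "r": np.nan, "n_obs": n,
                         "skipped": "insufficient overlap"})
            continue
        xs, ts = x[ok], tracer[ok]
        if np.std(xs) == 0 or np.std(ts) == 0:
            rows.append({"protein_id": pid, "r": np.nan, "n_obs": n,
                         "skipped": "constant values"})
            continue
        r = float(np.corrcoef(xs, ts)[0, 1])
        rows.append({"protein_id": pid, "r": r, "n_obs": n, "skipped": ""})
    out = pd.DataFrame(rows).sort_values(
        by=["r", "protein_id"], ascending=[False, True], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    out["above_threshold"] = out["r"] > r_threshold
    out["top_k"] = False
    out.loc[out.index[: top_k], "top_k"] = out["r"].iloc[:top_k].notna()
    return out
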