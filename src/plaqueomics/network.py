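"""Planar filtered co-expression network: edges, modules, hubs, traits.

Pipeline: permutation-screened pairwise Pearson correlations ->
greedy maximal planar graph (PFN) -> hierarchical module detection by
modularity-based recursive partitioning against a random-planar-graph
null -> hub calling within modules -> DAP-set enrichment (weighted
Kolmogorov-Smirnov score with a random-member-set null) -> module
eigengene / trait correlation.

Planarity caps the edge count at 3(V-2), forcing the network to keep
only the strongest local correlation structure, which is what makes
the multiscale module decomposition tractable and sparse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats as sp_stats

from .matrix import IntensityMatrix, PLAQUE
from .differential import bh_fdr

__all__ = [
    "EdgeSet",
    "Module",
    "prepare_network_matrix",
    "significant_correlations",
    "pairwise_pearson",
    "build_pfn",
    "detect_modules",
    "reported_modules",
    "find_hubs",
    "module_set_enrichment",
    "module_eigengene",
    "module_trait_correlation",
    "coexpression_analysis",
]


@dataclass
class EdgeSet:
    """Significant correlation edges (a < b lexicographically)."""

    edges: pd.DataFrame  # columns: protein_a, protein_b, rho, q_perm
    threshold: float  # |rho| cutoff achieving the permutation FDR

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class Module:
    """One node of the module hierarchy."""

    module_id: str
    parent: str | None
    members: tuple
    significance_p: float  # split p-value of the parent partition that created it
    level: int
    is_leaf: bool = True
    reported: bool = False
    hubs: tuple = ()
    hub_table: pd.DataFrame | None = None
    es: float = math.nan
    es_p: float = math.nan
    es_q: float = math.nan
    eigengene: pd.Series | None = None
    trait_r: float = math.nan
    trait_p: float = math.nan
    trait_q: float = math.nan
    trait_associated: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


# ----------------------------------------------------------------------
# Correlation screening
# ----------------------------------------------------------------------


def prepare_network_matrix(m: IntensityMatrix, max_missing: float = 0.5) -> pd.DataFrame:
    """Network input: drop proteins with >= max_missing missingness and
    median-center each protein (conditions stay merged)."""
    frac_missing = m.values.isna().mean(axis=1)
    keep = m.values.index[frac_missing < max_missing]
    x = m.values.loc[keep]
    return x.sub(x.median(axis=1, skipna=True), axis=0)


def pairwise_pearson(x: np.ndarray, min_overlap: int = 3):
    """Pairwise-complete Pearson correlations for a proteins-by-samples
    array with NaN. Returns (r, n) square matrices; pairs with fewer
    than ``min_overlap`` shared observations or zero variance are NaN.
    """
    mask = np.isfinite(x)
    x0 = np.where(mask, x, 0.0)
    mf = mask.astype(float)
    n = mf @ mf.T
    sx = x0 @ mf.T          # sum of x_i over samples shared with j
    sxx = (x0 * x0) @ mf.T
    sxy = x0 @ x0.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        vary = sxx.T - sx.T**2 / n
        denom = np.sqrt(varx * vary)
        r = np.where((n >= min_overlap) & (denom > 0), cov / denom, np.nan)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0), n.astype(int)


def significant_correlations(
    m: IntensityMatrix,
    n_perm: int = 100,
    fdr: float = 0.05,
    max_missing: float = 0.5,
    min_overlap: int = 3,
    seed: int = 0,
) -> EdgeSet:
    """Permutation-FDR screen of all pairwise correlations.

    The null pools |rho| values from ``n_perm`` rounds in which every
    protein's sample order is permuted independently (global null across
    pairs). For a candidate threshold t,
    ``FDR(t) = mean null count(|rho| >= t) / observed count(|rho| >= t)``;
    edges at or above the smallest t with FDR <= ``fdr`` are retained,
    and each edge's ``q_perm`` is the (monotone) FDR at its own |rho|.
    """
    xdf = prepare_network_matrix(m, max_missing=max_missing)
    ids = np.array(xdf.index)
    x = xdf.to_numpy(float)
    p = len(ids)
    if p < 2:
        raise ValueError("need at least two proteins after missingness filter")
    rng = np.random.default_rng(seed)

    iu = np.triu_indices(p, k=1)
    r_obs, _ = pairwise_pearson(x, min_overlap=min_overlap)
    obs = np.abs(r_obs[iu])
    valid = np.isfinite(obs)

    null_vals = []
    for _ in range(n_perm):
        xp = rng.permuted(x, axis=1)
        r_null, _ = pairwise_pearson(xp, min_overlap=min_overlap)
        nv = np.abs(r_null[iu])
        null_vals.append(nv[np.isfinite(nv)])
    null = np.sort(np.concatenate(null_vals))

    order = np.argsort(-obs[valid], kind="mergesort")
    obs_sorted = obs[valid][order]
    n_ge_obs = np.arange(1, len(obs_sorted) + 1)
    n_ge_null = len(null) - np.searchsorted(null, obs_sorted, side="left")
    fdr_at = np.minimum((n_ge_null / max(n_perm, 1)) / n_ge_obs, 1.0)
    # q at |rho|=r is the best FDR over admissible thresholds t <= r,
    # i.e. a reverse cumulative minimum in descending-|rho| order
    q_sorted = np.minimum.accumulate(fdr_at[::-1])[::-1]

    q = np.full(len(obs), np.nan)
    qv = np.empty(len(obs_sorted))
    qv[order] = q_sorted
    q[valid] = qv

    keep = valid.copy()
    keep[valid] = qv <= fdr
    threshold = float(obs_sorted[q_sorted <= fdr].min()) if keep.any() else math.inf

    a_idx, b_idx = iu[0][keep], iu[1][keep]
    edges = pd.DataFrame(
        {
            "protein_a": ids[a_idx],
            "protein_b": ids[b_idx],
            "rho": r_obs[iu][keep],
            "q_perm": q[keep],
        }
    )
    swap = edges["protein_a"] > edges["protein_b"]
    edges.loc[swap, ["protein_a", "protein_b"]] = edges.loc[
        swap, ["protein_b", "protein_a"]
    ].to_numpy()
    edges = edges.sort_values(
        ["protein_a", "protein_b"], kind="mergesort"
    ).reset_index(drop=True)
    return EdgeSet(edges=edges, threshold=threshold)


# ----------------------------------------------------------------------
# Planar filtered network
# ----------------------------------------------------------------------


def build_pfn(edge_set: EdgeSet | pd.DataFrame) -> nx.Graph:
    """Greedy maximal planar subgraph from the significant edges.

    Edges are inserted in descending |rho| order (ties broken by the
    lexicographic id pair) and kept only if the graph stays planar;
    insertion stops once 3(V-2) edges are present (a planar graph can
    hold no more). Edge attributes: ``rho`` and ``weight`` (= |rho|).
    """
    edges = edge_set.edges if isinstance(edge_set, EdgeSet) else edge_set
    if len(edges) == 0:
        raise ValueError("empty edge list")
    ordered = edges.assign(_abs=edges["rho"].abs()).sort_values(
        by=["_abs", "protein_a", "protein_b"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    nodes = sorted(set(edges["protein_a"]) | set(edges["protein_b"]))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    max_edges = max(3 * (len(nodes) - 2), 1) if len(nodes) >= 3 else len(nodes) - 1
    for a, b, rho in ordered[["protein_a", "protein_b", "rho"]].itertuples(index=False):
        if g.number_of_edges() >= max_edges:
            break
        g.add_edge(a, b, rho=float(rho), weight=abs(float(rho)))
        ok, _ = nx.check_planarity(g)
        if not ok:
            g.remove_edge(a, b)
    return g


def _random_planar_gnm(nodes, n_edges: int, rng: np.random.Generator) -> nx.Graph:
    """Random planar graph with the given node set and (up to) n_edges
    edges: a random Apollonian ("tetrahedral") triangulation grown by
    repeated face subdivision, randomly relabeled, then pruned by random
    edge deletion down to the requested edge count."""
    nodes = list(nodes)
    n = len(nodes)
    perm = rng.permutation(n)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if n < 3:
        if n == 2 and n_edges >= 1:
            g.add_edge(nodes[0], nodes[1])
        return g
    first = [int(i) for i in perm[:3]]
    edges = {tuple(sorted(p)) for p in
             [(first[0], first[1]), (first[0], first[2]), (first[1], first[2])]}
    faces = [tuple(first)]
    for v in perm[3:]:
        fi = int(rng.integers(len(faces)))
        a, b, c = faces[fi]
        v = int(v)
        edges.update([tuple(sorted((v, a))), tuple(sorted((v, b))), tuple(sorted((v, c)))])
        faces[fi] = (a, b, v)
        faces.append((a, c, v))
        faces.append((b, c, v))
    edge_list = sorted(edges)
    keep = rng.permutation(len(edge_list))[: min(n_edges, len(edge_list))]
    for idx in keep:
        i, j = edge_list[idx]
        g.add_edge(nodes[i], nodes[j])
    return g


def _null_graph(sub: nx.Graph, rng: np.random.Generator, method: str) -> nx.Graph:
    weights = np.array([d["weight"] for _, _, d in sub.edges(data=True)])
    if method == "planar":
        h = _random_planar_gnm(list(sub.nodes), sub.number_of_edges(), rng)
    elif method == "rewire":
        h = nx.Graph(sub)
        try:
            nx.double_edge_swap(
                h,
                nswap=sub.number_of_edges(),
                max_tries=20 * sub.number_of_edges(),
                seed=int(rng.integers(2**31)),
            )
        except nx.NetworkXError:
            pass
    else:
        raise ValueError(f"unknown null method {method!r}")
    w = rng.permutation(weights)
    for i, (a, b) in enumerate(h.edges()):
        h[a][b]["weight"] = float(w[i % len(w)]) if len(w) else 1.0
    return h


def _partition(sub: nx.Graph, seed: int):
    comms = nx.community.louvain_communities(sub, weight="weight", seed=seed)
    q = nx.community.modularity(sub, comms, weight="weight")
    return comms, q


def detect_modules(
    net: nx.Graph,
    min_size: int = 10,
    alpha: float = 0.05,
    n_null: int = 100,
    seed: int = 0,
    null_method: str = "planar",
) -> list[Module]:
    """Hierarchical module detection by recursive modularity splitting.

    Each connected component is a root module. A (sub)graph with at
    least ``2 * min_size`` nodes is split by the maximum-modularity
    partition; the split is accepted when its modularity exceeds the
    empirical ``1 - alpha`` quantile of modularities obtained on
    ``n_null`` random planar graphs with the same node and edge count
    (weights permuted), i.e. split p-value < alpha. Accepted children
    recurse. Modules are ``reported`` when their size lies in
    ``[min_size, |V|/2]``; excluded modules keep their place in the
    hierarchy so parents remain addressable.
    """
    rng = np.random.default_rng(seed)
    total_nodes = net.number_of_nodes()
    modules: list[Module] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"M{counter[0]}"

    def recurse(nodes: tuple, parent: str | None, level: int, split_p: float) -> None:
        mod = Module(
            module_id=new_id(),
            parent=parent,
            members=tuple(sorted(nodes)),
            significance_p=split_p,
            level=level,
        )
        modules.append(mod)
        sub = net.subgraph(nodes)
        if sub.number_of_nodes() < 2 * min_size or sub.number_of_edges() == 0:
            return
        comms, q_obs = _partition(sub, seed=int(rng.integers(2**31)))
        if len(comms) < 2:
            return
        null_q = np.empty(n_null)
        for j in range(n_null):
            h = _null_graph(sub, rng, null_method)
            _, null_q[j] = _partition(h, seed=int(rng.integers(2**31)))
        p = (1.0 + np.sum(null_q >= q_obs)) / (1.0 + n_null)
        if p < alpha:
            mod.is_leaf = False
            for comm in sorted(comms, key=lambda c: sorted(c)[0]):
                recurse(tuple(sorted(comm)), mod.module_id, level + 1, p)

    components = sorted(nx.connected_components(net), key=lambda c: (-len(c), sorted(c)[0]))
    for comp in components:
        recurse(tuple(sorted(comp)), None, 0, math.nan)

    for mod in modules:
        mod.reported = min_size <= mod.size <= total_nodes / 2
    return modules


def reported_modules(modules: list[Module], leaves_only: bool = False) -> list[Module]:
    out = [m for m in modules if m.reported]
    if leaves_only:
        out = [m for m in out if m.is_leaf]
    return out


# ----------------------------------------------------------------------
# Hubs
# ----------------------------------------------------------------------


def find_hubs(
    net: nx.Graph,
    module: Module,
    alpha: float = 0.05,
    n_null: int = 1000,
    seed: int = 0,
) -> Module:
    """Call hub proteins: nodes whose within-module strength (sum of
    |rho| to module members) exceeds a random-network null.

    The null draws random graphs on the module's nodes with the same
    edge count and the observed weights permuted onto the random edges,
    pooling node strengths across all draws and nodes. A node is a hub
    when its empirical p < alpha; BH-adjusted q-values across the
    module's nodes are reported alongside.
    """
    rng = np.random.default_rng(seed)
    sub = net.subgraph(module.members)
    nodes = sorted(sub.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    strength = np.zeros(n)
    weights = []
    for a, b, d in sub.edges(data=True):
        strength[idx[a]] += d["weight"]
        strength[idx[b]] += d["weight"]
        weights.append(d["weight"])
    m_edges = len(weights)
    weights = np.array(weights)
    if m_edges == 0 or n < 3:
        module.hubs = ()
        module.hub_table = pd.DataFrame(
            {"protein_id": nodes, "strength": strength, "p": 1.0, "q": 1.0, "is_hub": False}
        )
        return module

    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    null_strengths = np.empty((n_null, n))
    for j in range(n_null):
        pick = rng.choice(n_pairs, size=min(m_edges, n_pairs), replace=False)
        w = rng.permutation(weights)[: len(pick)]
        s = np.zeros(n)
        np.add.at(s, iu[0][pick], w)
        np.add.at(s, iu[1][pick], w)
        null_strengths[j] = s
    pooled = np.sort(null_strengths.ravel())
    ge = len(pooled) - np.searchsorted(pooled, strength, side="left")
    p = (1.0 + ge) / (1.0 + len(pooled))
    q = bh_fdr(p)
    is_hub = p < alpha
    module.hub_table = pd.DataFrame(
        {"protein_id": nodes, "strength": strength, "p": p, "q": q, "is_hub": is_hub}
    )
    module.hubs = tuple(np.array(nodes)[is_hub])
    return module


def filter_hub_table(
    hub_df: pd.DataFrame, z_by_stratum: pd.DataFrame, z_cut: float = 1.5
) -> pd.DataFrame:
    """Post-filter for hub export: keep hubs with |log2FC-z| > z_cut and
    a consistent fold-change direction across strata.

    ``z_by_stratum`` is proteins-by-strata log2FC-z values.
    """
    keep = []
    for pid in hub_df.loc[hub_df["is_hub"], "protein_id"]:
        if pid not in z_by_stratum.index:
            continue
        zs = z_by_stratum.loc[pid].dropna().to_numpy(float)
        if len(zs) == 0:
            continue
        if np.max(np.abs(zs)) > z_cut and (np.all(zs >= 0) or np.all(zs <= 0)):
            keep.append(pid)
    return hub_df[hub_df["protein_id"].isin(keep)].reset_index(drop=True)


# ----------------------------------------------------------------------
# Module enrichment (weighted KS against a ranked statistic)
# ----------------------------------------------------------------------


def _es_from_positions(pos: np.ndarray, w_ranked: np.ndarray, n_total: int) -> np.ndarray:
    """Signed enrichment score(s) for sorted 0-based hit positions.

    ``pos`` is (n_draws, k); the running sum rises by the normalized
    weight at each hit and falls by 1/(N-k) at each miss; the score is
    the extreme deviation (positive or negative, whichever larger).
    """
    n_draws, k = pos.shape
    w_hit = w_ranked[pos]  # (n_draws, k)
    wsum = w_hit.sum(axis=1, keepdims=True)
    wsum = np.where(wsum > 0, wsum, 1.0)
    cum_hit = np.cumsum(w_hit, axis=1) / wsum
    miss_frac = (pos - np.arange(k)) / float(n_total - k)  # misses before each hit
    dev_pos = (cum_hit - miss_frac).max(axis=1)
    prev_hit = np.concatenate([np.zeros((n_draws, 1)), cum_hit[:, :-1]], axis=1)
    dev_neg = (miss_frac - prev_hit).max(axis=1)
    # running sum also decays to 0 after the last hit; intermediate
    # extremes above cover the maximum deviation in both directions
    return np.where(dev_pos >= dev_neg, dev_pos, -dev_neg)


def module_set_enrichment(
    members,
    ranked_stats: pd.Series,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Weighted KS enrichment of a member set against a ranked statistic.

    ``ranked_stats`` maps protein -> statistic (e.g. |log2FC-z|); the
    universe is ranked by the statistic descending and the running-sum
    score uses the statistic itself as hit weight (exponent 1). The
    p-value is the fraction of ``n_perm`` random same-size member sets
    whose score is at least the observed one (one-sided toward
    enrichment at the top).

    Returns ``(es, p)``.
    """
    stats_sorted = ranked_stats.sort_values(ascending=False, kind="mergesort")
    ids = list(stats_sorted.index)
    pos_of = {pid: i for i, pid in enumerate(ids)}
    hits = sorted(pos_of[p] for p in members if p in pos_of)
    if not hits:
        raise ValueError("module has no member in the ranking universe")
    n_total = len(ids)
    k = len(hits)
    if k >= n_total:
        raise ValueError("module covers the whole universe")
    w = np.abs(stats_sorted.to_numpy(float))
    es = float(_es_from_positions(np.array([hits]), w, n_total)[0])

    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n_total))
    pick = np.argpartition(keys, k, axis=1)[:, :k]
    pick.sort(axis=1)
    null_es = _es_from_positions(pick, w, n_total)
    p = float((1 + np.sum(null_es >= es)) / (1 + n_perm))
    return es, p


# ----------------------------------------------------------------------
# Eigengenes and trait correlation
# ----------------------------------------------------------------------


def module_eigengene(m: IntensityMatrix, members, max_missing: float = 0.5) -> pd.Series:
    """First-principal-component score of the module across samples.

    Members with >= ``max_missing`` missingness are dropped; remaining
    missing cells are imputed with the protein mean; rows are
    standardized. The score is scaled to unit variance and sign-oriented
    so that it correlates non-negatively with the mean member profile.
    """
    sub = m.values.loc[[p for p in m.values.index if p in set(members)]]
    frac = sub.isna().mean(axis=1)
    sub = sub[frac < max_missing]
    if sub.empty:
        raise ValueError("no module member passes the missingness filter")
    arr = sub.to_numpy(float)
    row_mean = np.nanmean(arr, axis=1, keepdims=True)
    arr = np.where(np.isfinite(arr), arr, row_mean)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    if scores.std(ddof=1) == 0:
        raise ValueError("constant eigengene")
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    mean_profile = z.mean(axis=0)
    if np.corrcoef(scores, mean_profile)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=sub.columns, name="eigengene")


def module_trait_correlation(
    modules: list[Module],
    m: IntensityMatrix,
    trait: pd.Series | None = None,
    fdr: float = 0.05,
    r_cut: float = 0.4,
    max_missing: float = 0.5,
) -> list[Module]:
    """Correlate module eigengenes with the plaque indicator.

    ``trait`` defaults to 1 for plaque samples, 0 otherwise. Pearson r
    with an exact t-based p-value per module, BH across modules; a
    module is flagged trait-associated iff ``trait_q < fdr`` and
    ``|trait_r| >= r_cut``.
    """
    if trait is None:
        meta = m.meta()
        trait = (meta["region"] == PLAQUE).astype(float)
    ps = []
    for mod in modules:
        eg = module_eigengene(m, mod.members, max_missing=max_missing)
        t = trait.loc[eg.index].to_numpy(float)
        r, p = sp_stats.pearsonr(eg.to_numpy(float), t)
        mod.eigengene = eg
        mod.trait_r, mod.trait_p = float(r), float(p)
        ps.append(p)
    qs = bh_fdr(ps)
    for mod, q in zip(modules, qs):
        mod.trait_q = float(q)
        mod.trait_associated = bool(q < fdr and abs(mod.trait_r) >= r_cut)
    return modules


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------


def coexpression_analysis(
    m: IntensityMatrix,
    ranked_stats: pd.Series | None = None,
    n_perm_edges: int = 100,
    edge_fdr: float = 0.05,
    min_size: int = 10,
    alpha: float = 0.05,
    n_null_modules: int = 100,
    n_null_hubs: int = 1000,
    n_perm_es: int = 10000,
    trait_fdr: float = 0.05,
    r_cut: float = 0.4,
    seed: int = 0,
) -> tuple[nx.Graph, list[Module], pd.DataFrame]:
    """End-to-end network stage; returns (pfn, modules, module_table)."""
    edge_set = significant_correlations(
        m, n_perm=n_perm_edges, fdr=edge_fdr, seed=seed
    )
    if len(edge_set) == 0:
        warnings.warn("no significant correlations; empty network")
        return nx.Graph(), [], pd.DataFrame()
    pfn = build_pfn(edge_set)
    modules = detect_modules(
        pfn, min_size=min_size, alpha=alpha, n_null=n_null_modules, seed=seed + 1
    )
    report = reported_modules(modules)
    for i, mod in enumerate(report):
        find_hubs(pfn, mod, alpha=alpha, n_null=n_null_hubs, seed=seed + 100 + i)
    if ranked_stats is not None and len(report):
        es_ps = []
        for i, mod in enumerate(report):
            mod.es, mod.es_p = module_set_enrichment(
                mod.members, ranked_stats, n_perm=n_perm_es, seed=seed + 500 + i
            )
            es_ps.append(mod.es_p)
        for mod, q in zip(report, bh_fdr(es_ps)):
            mod.es_q = float(q)
    if report:
        module_trait_correlation(report, m, fdr=trait_fdr, r_cut=r_cut)

    rows = [
        {
            "module_id": mod.module_id,
            "parent": mod.parent or "root",
            "size": mod.size,
            "significance_p": mod.significance_p,
            "es": mod.es,
            "es_q": mod.es_q,
            "trait_r": mod.trait_r,
            "trait_q": mod.trait_q,
            "trait_associated": mod.trait_associated,
            "members": ";".join(mod.members),
            "hubs": ";".join(mod.hubs),
        }
        for mod in report
    ]
    return pfn, modules, pd.DataFrame(rows)
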