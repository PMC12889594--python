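"""Overrepresentation analysis of DAP sets against gene-set collections.

One-sided Fisher's exact (hypergeometric upper tail) per set, BH across
sets, reported when q < 0.01 and fold enrichment > 2. The background
defaults to the proteins quantified in the comparison — the
statistically conservative choice — not the whole proteome. Gene sets
are supplied as GMT files; no live database queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_fdr

__all__ = ["GeneSetCollection", "read_gmt", "fisher_ora"]


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a background protein universe."""

    sets: dict  # set_id -> (name, frozenset of members)
    background: frozenset

    def __post_init__(self) -> None:
        self.background = frozenset(self.background)
        clipped = {}
        for sid, (name, members) in self.sets.items():
            inter = frozenset(members) & self.background
            if inter:
                clipped[sid] = (name, inter)
        self.sets = clipped

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, background=None) -> GeneSetCollection:
    """Read GMT (``set_id<TAB>description<TAB>member...``); background
    defaults to the union of all set members."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        sets[parts[0]] = (parts[1], frozenset(p for p in parts[2:] if p))
    if background is None:
        background = frozenset().union(*(m for _, m in sets.values())) if sets else frozenset()
    return GeneSetCollection(sets=sets, background=background)


def fisher_ora(
    daps,
    collection: GeneSetCollection,
    fdr: float = 0.01,
    min_fold: float = 2.0,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Fisher overrepresentation test of a DAP set against every gene set.

    For each set: ``a`` = DAPs in the set, ``k`` = DAP count in the
    background, ``K`` = set size, ``M`` = background size. The p-value
    is the hypergeometric upper tail P(X >= a); fold enrichment is
    ``(a/k) / (K/M)``. BH across sets; a set is ``reported`` iff
    ``q < fdr`` and fold enrichment > ``min_fold``.
    """
    daps = set(daps)
    outside = daps - set(collection.background)
    if outside:
        warnings.warn(f"{len(outside)} query proteins outside the background; dropped")
        daps &= set(collection.background)
    if not daps:
        raise ValueError("empty DAP set after background intersection")
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    m_bg = len(collection.background)
    k = len(daps)
    rows = []
    for sid, (name, members) in collection.sets.items():
        big_k = len(members)
        a = len(daps & members)
        p_upper = float(hypergeom.sf(a - 1, m_bg, big_k, k))
        if two_sided:
            p_lower = float(hypergeom.cdf(a, m_bg, big_k, k))
            p = min(1.0, 2.0 * min(p_upper, p_lower))
        else:
            p = p_upper
        fold = (a / k) / (big_k / m_bg) if big_k else 0.0
        rows.append(
            {"set_id": sid, "name": name, "a": a, "k": k, "K": big_k, "M": m_bg,
             "fold_enrichment": fold, "p": p}
        )
    out = pd.DataFrame(rows).sort_values("set_id", kind="mergesort").reset_index(drop=True)
    out["q"] = bh_fdr(out["p"])
    out["reported"] = (out["q"] < fdr) & (out["fold_enrichment"] > min_fold)
    return out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
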