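"""Over-representation statistics and gene-cluster summaries.

Tests whether named gene sets (e.g. per-tissue Enriched sets, or a
co-located testis-specific cluster) are over-represented among the extreme
tails of a fold-change ranking, via upper-tail hypergeometric tests with BH
correction over all set x direction tests in a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "GeneSetCollection",
    "hypergeom_overrep",
    "percentile_enrichment",
    "set_overlap",
    "cluster_lfc_summary",
]


class GeneSetCollection:
    """Named gene sets intersected with a universe of expressed genes."""

    def __init__(self, sets: dict[str, set[str]], universe: set[str]):
        if len(sets) != len(set(sets)):
            raise ValueError("set names must be unique")
        self.universe = set(universe)
        self.sets = {
            name: set(members) & self.universe for name, members in sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def hypergeom_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts members of a size-n set among K draws without replacement from
    a universe of N genes. Errors on inconsistent counts.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, n, K))


def percentile_enrichment(
    lfc: pd.Series,
    sets: GeneSetCollection,
    pct: float = 0.01,
) -> pd.DataFrame:
    """Over-representation of each gene set among the top and bottom
    ``pct`` extremes of the (shrunken) LFC ranking.

    Extremes are the ceil(pct * N) genes with highest / lowest LFC over the
    universe; ties at the boundary are broken by gene id so the extreme size
    is exact and deterministic. One BH family covers all set x direction
    tests. ``mean_lfc`` is the mean LFC of the set's members inside the
    extreme (NaN when none).
    """
    if not (0 < pct < 0.5):
        raise ValueError("pct must be in (0, 0.5)")
    universe = [g for g in lfc.index if g in sets.universe]
    vals = lfc.loc[universe]
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe after intersecting with LFC table")
    K = math.ceil(pct * N)
    # stable sort after an index sort: boundary ties break lexicographically
    ranked = vals.sort_index().sort_values(ascending=False, kind="mergesort")
    top = set(ranked.index[:K])
    bottom = set(ranked.index[-K:])

    rows = []
    for name, members in sets.items():
        n = len(members)
        for direction, extreme in (("top", top), ("bottom", bottom)):
            hits = members & extreme
            k = len(hits)
            p = hypergeom_overrep(k, K, n, N) if n else 1.0
            mean_lfc = float(vals.loc[sorted(hits)].mean()) if hits else np.nan
            rows.append(
                {
                    "set": name,
                    "direction": direction,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p": p,
                    "mean_lfc": mean_lfc,
                }
            )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def set_overlap(a: set[str], b: set[str]) -> dict[str, float]:
    """Overlap count, per-side fractions and Jaccard index of two sets."""
    inter = len(a & b)
    union = len(a | b)
    return {
        "overlap": inter,
        "fraction_of_a": inter / len(a) if a else 0.0,
        "fraction_of_b": inter / len(b) if b else 0.0,
        "jaccard": inter / union if union else 0.0,
    }


def cluster_lfc_summary(
    lfc: pd.Series,
    cluster: pd.DataFrame,
    ectopic_genes: set[str] | None = None,
    lfc_all: pd.Series | None = None,
) -> dict:
    """Positional gene-cluster summary: mean LFC, per-gene LFC, counts of
    upregulated / ectopic members, and inter-gene distances.

    ``cluster`` is an ordered frame indexed by gene id with ``start`` and
    ``end`` columns (0-based half-open spans). The distance between adjacent
    genes is the left-most coordinate of the next gene body minus the
    right-most coordinate of the previous one, regardless of orientation.
    Cluster genes missing from the LFC table are reported and excluded.
    """
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    present = [g for g in cluster.index if g in lfc.index]
    missing = [g for g in cluster.index if g not in lfc.index]
    per_gene = lfc.loc[present]
    ordered = cluster.loc[present].sort_values("start")
    distances = (
        ordered["start"].to_numpy()[1:] - ordered["end"].to_numpy()[:-1]
    ).tolist()
    summary = {
        "n_genes": len(present),
        "missing_genes": missing,
        "mean_lfc": float(per_gene.mean()) if present else np.nan,
        "per_gene_lfc": per_gene,
        "n_upregulated": int((per_gene > 0).sum()),
        "n_ectopic": (
            len(set(present) & ectopic_genes) if ectopic_genes is not None else None
        ),
        "inter_gene_distances": distances,
    }
    if lfc_all is not None:
        summary["genome_mean_lfc"] = float(lfc_all.mean())
    return summary
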