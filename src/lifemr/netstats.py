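"""Enrichment, network-centrality and effect-direction statistics.

Hypergeometric over-representation tests (exact upper tail), degree and
exact shortest-path betweenness centrality on co-expression graphs,
strict top-percentile membership, disease-disease network construction
from shared genes, and concordance classification of paired
disorder/lifespan causal effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .loci import bh_adjust
from .mr import bonferroni_threshold

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment",
    "centrality",
    "top_percentile",
    "disease_network",
    "concordance",
]


@dataclass
class EnrichmentResult:
    k: int  # hits in sample
    n: int  # sample size
    K: int  # hits in population
    N: int  # population size
    fold: float
    p: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("hit count exceeds sample or target size")
        if not 0 < self.p <= 1:
            raise ValueError("p outside (0, 1]")


def hypergeom_enrichment(sample_set, target_set, universe) -> EnrichmentResult:
    """Exact hypergeometric over-representation of target genes in a sample.

    p = P(X >= k) with k = |sample & target|, drawn from a universe of N
    genes containing K targets; fold = (k/n)/(K/N). Both sets must be
    subsets of the universe.
    """
    universe = set(universe)
    sample = set(sample_set)
    target = set(target_set)
    if not universe or not sample:
        raise ValueError("universe and sample must be nonempty")
    if not sample <= universe or not target <= universe:
        raise ValueError("sample and target must be subsets of the universe")
    N, K, n = len(universe), len(target), len(sample)
    k = len(sample & target)
    # upper tail including k itself; sf(k-1) = P(X >= k)
    p = float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))
    fold = (k / n) / (K / N) if K else float("nan")
    return EnrichmentResult(k, n, K, N, fold, p)


def centrality(graph: nx.Graph) -> pd.DataFrame:
    """Exact per-node degree and unnormalized shortest-path betweenness.

    Betweenness counts each unordered node pair once (Brandes algorithm
    on the unweighted simple graph).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if any(u == v for u, v in graph.edges):
        raise ValueError("self-loops are not allowed")
    btw = nx.betweenness_centrality(graph, normalized=False)
    return pd.DataFrame(
        {
            "node": list(graph.nodes),
            "degree": [graph.degree(v) for v in graph.nodes],
            "betweenness": [btw[v] for v in graph.nodes],
        }
    )


def top_percentile(values: pd.Series | dict, q: float = 0.99) -> set:
    """Members strictly above the q-quantile (linear interpolation).

    Ties at the threshold are excluded, so a constant vector yields the
    empty set.
    """
    s = pd.Series(values, dtype=float)
    if s.empty:
        raise ValueError("no values supplied")
    thresh = float(np.quantile(s.to_numpy(), q))
    return set(s.index[s > thresh])


def disease_network(gene_disease_pairs: pd.DataFrame) -> nx.Graph:
    """Disease-disease graph: one gene linked to two diseases contributes
    one edge between them; the edge weight counts the shared genes.

    ``gene_disease_pairs`` has columns (gene, disease); genes annotated
    to a single disease contribute no edge, and there are no self-edges.
    """
    if gene_disease_pairs.empty:
        raise ValueError("empty gene-disease pair list")
    gcol, dcol = gene_disease_pairs.columns[:2]
    g = nx.Graph()
    g.add_nodes_from(gene_disease_pairs[dcol].unique())
    for _, diseases in gene_disease_pairs.groupby(gcol)[dcol]:
        for a, b in combinations(sorted(set(diseases)), 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def concordance(
    calls: pd.DataFrame,
    alpha: float = 0.05,
    m: int | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify paired disorder/lifespan causal effects as concordant.

    A pair is *concordant* when the effect signs oppose — the exposure
    that decreases disorder risk increases lifespan (and vice versa).
    ``calls`` needs columns (gene, disorder, theta_disorder, p_disorder,
    theta_lifespan); pairs with a zero effect are flagged indeterminate.
    Each pair gets the strictest significance tier its disorder p-value
    passes: 'bonferroni' (p < alpha/m over the pair family), 'fdr'
    (BH-adjusted p < alpha) or 'nominal' (p < alpha).

    Returns the annotated table and the concordant fraction per tier
    (each tier includes the stricter ones above it).
    """
    required = {"gene", "disorder", "theta_disorder", "p_disorder", "theta_lifespan"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = calls.copy()
    if m is None:
        m = len(df)
    bonf = bonferroni_threshold(alpha, m)
    p_fdr = bh_adjust(df["p_disorder"].to_numpy())
    tier = np.where(
        df["p_disorder"] < bonf, "bonferroni",
        np.where(p_fdr < alpha, "fdr", np.where(df["p_disorder"] < alpha, "nominal", "none")),
    )
    sign_d = np.sign(df["theta_disorder"])
    sign_l = np.sign(df["theta_lifespan"])
    indeterminate = (sign_d == 0) | (sign_l == 0)
    label = np.where(indeterminate, "indeterminate",
                     np.where(sign_d != sign_l, "concordant", "non-concordant"))
    df["p_fdr"] = p_fdr
    df["tier"] = tier
    df["label"] = label

    summary: dict[str, float] = {}
    order = ["bonferroni", "fdr", "nominal"]
    for i, t in enumerate(order):
        mask = df["tier"].isin(order[: i + 1]) & (df["label"] != "indeterminate")
        summary[t] = float((df.loc[mask, "label"] == "concordant").mean()) if mask.any() else float("nan")
    return df, summary
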