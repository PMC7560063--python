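"""Differential expression and protein-interaction network comparison.

Severity DEGs come from a per-gene two-group linear model on mild vs severe
samples, optionally with moderated variance (gene-wise variances shrunk toward
the global mean variance with a fixed prior degrees of freedom), followed by
Benjamini-Hochberg adjustment. Gene lists are then compared on a user-supplied
PPI edge list by degree and betweenness centrality with a one-sided Wilcoxon
rank-sum test — the route used to argue that autoencoder-derived signature
genes occupy more central network positions than plain DEGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

#: Fixed prior degrees of freedom for the moderated variance shrinkage.
MODERATION_PRIOR_DF = 4.0


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(X: ExpressionMatrix, labels, alpha: float = 0.1,
                            moderation: bool = True,
                            prior_df: float = MODERATION_PRIOR_DF) -> pd.DataFrame:
    """Two-group (mild vs severe) per-gene linear model with optional moderation.

    Parameters
    ----------
    X:
        Expression restricted to the samples being compared.
    labels:
        Per-sample group labels with exactly two levels; the log-fold-change
        is mean(second level) - mean(first level) with levels sorted
        ("mild" < "severe" gives severe-minus-mild).
    moderation:
        If True, each gene's variance is shrunk toward the mean gene variance
        with ``prior_df`` prior degrees of freedom before forming the t
        statistic; the t reference distribution gains the prior df.

    Returns a DataFrame with gene, log_fold_change, t_statistic, p,
    p_adjusted, significant (p_adjusted < alpha).
    """
    labels = np.asarray([str(l) for l in labels])
    if labels.size != X.n_samples:
        raise ValueError("labels length must match sample count")
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    g0 = X.values[:, labels == levels[0]]
    g1 = X.values[:, labels == levels[1]]
    n0, n1 = g0.shape[1], g1.shape[1]
    if min(n0, n1) < 2:
        raise ValueError("each group needs >= 2 samples")

    diff = g1.mean(axis=1) - g0.mean(axis=1)
    ss = ((g0 - g0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = n0 + n1 - 2
    s2 = ss / df_resid  # pooled per-gene variance
    if moderation:
        s2_prior = float(s2.mean())
        s2_used = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
        df_total = df_resid + prior_df
    else:
        s2_used = s2
        df_total = df_resid
    se = np.sqrt(s2_used * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": X.gene_ids,
            "log_fold_change": diff,
            "t_statistic": t,
            "p": p,
            "p_adjusted": padj,
            "significant": padj < alpha,
        }
    )


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    """Simple undirected protein-interaction graph (no self-loops, deduplicated)."""

    graph: nx.Graph
    n_duplicates_dropped: int = 0
    n_self_loops_dropped: int = 0

    @classmethod
    def from_edges(cls, nodes, edges) -> "PPINetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        dupes = loops = 0
        for a, b in edges:
            if a == b:
                loops += 1
                continue
            if g.has_edge(a, b):
                dupes += 1
                continue
            g.add_edge(a, b)
        return cls(g, n_duplicates_dropped=dupes, n_self_loops_dropped=loops)

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return [tuple(sorted(e)) for e in self.graph.edges]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")


def load_edges(path) -> PPINetwork:
    """Read a 2+ column TSV edge list into a simple undirected graph.

    Duplicate edges and self-loops are dropped (counts kept on the returned
    object); a header line whose first field is ``node_a`` is skipped.
    """
    edges = []
    nodes = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed edge line {lineno}: {line!r}")
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and a == "node_a":
                continue
            if not a or not b:
                raise ValueError(f"malformed edge line {lineno}: {line!r}")
            edges.append((a, b))
            nodes.update((a, b))
    return PPINetwork.from_edges(sorted(nodes), edges)


def first_shell(network: PPINetwork, query) -> PPINetwork:
    """Induced subgraph on the query genes plus their direct neighbors."""
    query = list(query)
    if not query:
        raise ValueError("query must be non-empty")
    present = [q for q in query if q in network.graph]
    if not present:
        raise ValueError("no query gene present in the network")
    keep = set(present)
    for q in present:
        keep.update(network.graph.neighbors(q))
    sub = network.graph.subgraph(keep).copy()
    return PPINetwork(sub)


def centrality(network: PPINetwork) -> pd.DataFrame:
    """Degree and exact unnormalized shortest-path betweenness per node."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    deg = dict(network.graph.degree())
    btw = nx.betweenness_centrality(network.graph, normalized=False)
    nodes = list(network.graph.nodes)
    return pd.DataFrame(
        {"node": nodes,
         "degree": [deg[n] for n in nodes],
         "betweenness": [btw[n] for n in nodes]}
    ).set_index("node")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a, b, alternative: str = "two-sided"):
    """Wilcoxon rank-sum test: (rank-sum statistic of ``a``, p-value).

    Uses exact enumeration when the combined sample size is at most 12 and
    tie-free, else the normal approximation with tie and continuity
    correction. The statistic returned is the mid-rank sum of sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    return w, float(res.pvalue)


def compare_gene_lists_centrality(network: PPINetwork, list_a, list_b) -> dict:
    """Compare two gene lists' network centrality (is A more central than B?).

    Returns per-list degree/betweenness values and one-sided Wilcoxon
    (A greater) p-values for each centrality, plus the genes absent from the
    network (excluded from the comparison).
    """
    cent = centrality(network)
    in_a = [g for g in list_a if g in cent.index]
    in_b = [g for g in list_b if g in cent.index]
    missing_a = [g for g in list_a if g not in cent.index]
    missing_b = [g for g in list_b if g not in cent.index]
    if not in_a or not in_b:
        raise ValueError("each gene list must intersect the network")
    report = {"genes_used_a": in_a, "genes_used_b": in_b,
              "genes_missing_a": missing_a, "genes_missing_b": missing_b}
    for metric in ("degree", "betweenness"):
        va = cent.loc[in_a, metric].to_numpy(float)
        vb = cent.loc[in_b, metric].to_numpy(float)
        stat, p = wilcoxon_rank_sum(va, vb, alternative="greater")
        report[metric] = {
            "mean_a": float(va.mean()),
            "mean_b": float(vb.mean()),
            "rank_sum_a": stat,
            "p_greater": p,
        }
    return report
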