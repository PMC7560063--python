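"""Functional annotation of hidden units from their encoder weights.

Pre-ranked gene-set enrichment treats the encoder-weight row of a hidden unit
as the per-gene ranking statistic and scores each gene set with the weighted
Kolmogorov-Smirnov running-sum enrichment score (ES): walking the ranking in
decreasing-weight order, set members add |r|^p normalized by the total hit
weight and non-members subtract 1/(N - N_hit); ES is the most extreme
deviation of the running sum. Significance comes from gene-label permutations
(random sets of equal size), one-sided on the matching ES sign with a +1
pseudo-count, with a sign-matched normalized ES (NES) and Benjamini-Hochberg
adjustment across sets. A hypergeometric over-representation test covers
plain gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de_network import bh_adjust

MIN_SET_SIZE = 5
MAX_SET_SIZE = 500


@dataclass
class GeneSetCollection:
    """Named gene sets (unique names, non-empty member lists)."""

    sets: dict
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, self.source or "na", *members]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB members...

    Duplicate member genes within a set are deduplicated (first occurrence
    kept); a duplicated set name or a line with fewer than 3 fields is an
    error reported with its line number.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT parse error at line {lineno}: "
                                 f"expected >= 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT parse error at line {lineno}: "
                                 f"duplicate set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = members
    return GeneSetCollection(sets, source=str(path))


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    p_adjusted: float
    size_used: int
    leading_edge: list = field(default_factory=list)
    running_sum: np.ndarray | None = None


def _es_from_hits(absr_p: np.ndarray, hit_mask: np.ndarray):
    """Full running sum and signed ES for one set (oracle-friendly O(N) walk)."""
    N = absr_p.size
    n_hit = int(hit_mask.sum())
    nr = absr_p[hit_mask].sum()
    if nr <= 0:
        # degenerate all-zero hit weights: hits contribute equally
        inc = np.where(hit_mask, 1.0 / n_hit, -1.0 / (N - n_hit))
    else:
        inc = np.where(hit_mask, absr_p / nr, -1.0 / (N - n_hit))
    running = np.cumsum(inc)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if abs(running[i_max]) >= abs(running[i_min]):
        return running, float(running[i_max]), i_max
    return running, float(running[i_min]), i_min


def _perm_es(absr_p: np.ndarray, set_size: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized ES for ``n_perm`` random same-size sets.

    The running sum between hits is linear, so its extrema occur just before
    or just after hit positions; those 2*set_size candidate values per
    permutation are computed from the sorted hit positions alone.
    """
    N = absr_p.size
    miss = 1.0 / (N - set_size)
    # random distinct positions per permutation via argsort of uniforms
    pos = np.argsort(rng.random((n_perm, N)), axis=1)[:, :set_size]
    pos.sort(axis=1)
    w = absr_p[pos]
    nr = w.sum(axis=1, keepdims=True)
    safe = nr > 0
    H = np.where(safe, np.cumsum(w, axis=1) / np.where(safe, nr, 1.0),
                 np.cumsum(np.ones_like(w), axis=1) / set_size)
    j = np.arange(1, set_size + 1)
    after = H - (pos + 1 - j) * miss          # running sum just after each hit
    before = np.concatenate([np.zeros((n_perm, 1)), H[:, :-1]], axis=1) \
        - (pos - (j - 1)) * miss              # just before each hit
    hi = np.maximum(after.max(axis=1), np.maximum(before.max(axis=1), 0.0))
    lo = np.minimum(before.min(axis=1), np.minimum(after.min(axis=1), 0.0))
    return np.where(hi >= -lo, hi, lo)


def preranked_gsea(statistics: dict, sets: GeneSetCollection,
                   n_perm: int = 1000, weight_exponent: float = 1.0,
                   seed: int = 0, min_size: int = MIN_SET_SIZE,
                   max_size: int = MAX_SET_SIZE,
                   keep_running_sum: bool = False) -> pd.DataFrame:
    """Pre-ranked GSEA of every set against a gene -> statistic mapping.

    Genes are ranked by decreasing statistic (here: encoder weights). Returns
    a DataFrame sorted by nominal p with columns set_name, size_used, es,
    nes, p_nominal, p_adjusted, leading_edge; sets with fewer than
    ``min_size`` or more than ``max_size`` members present in the ranking are
    skipped with a warning.
    """
    genes = np.array(list(statistics.keys()))
    if genes.size != len(set(genes)):
        raise ValueError("ranking statistic has duplicate genes")
    values = np.array([statistics[g] for g in genes], dtype=float)
    order = np.argsort(-values, kind="stable")
    ranked_genes = genes[order]
    ranked_values = values[order]
    absr_p = np.abs(ranked_values) ** weight_exponent
    index = {g: i for i, g in enumerate(ranked_genes)}
    N = genes.size
    rng = np.random.default_rng(seed)

    rows = []
    results = []
    for name, members in sets.sets.items():
        present = [g for g in members if g in index]
        if len(present) < min_size or len(present) > max_size or len(present) >= N:
            warnings.warn(f"skipping gene set {name!r}: {len(present)} usable genes")
            continue
        hit_mask = np.zeros(N, dtype=bool)
        hit_mask[[index[g] for g in present]] = True
        running, es, i_peak = _es_from_hits(absr_p, hit_mask)
        if es >= 0:
            leading = [g for g in ranked_genes[: i_peak + 1] if hit_mask[index[g]]]
        else:
            leading = [g for g in ranked_genes[i_peak:] if hit_mask[index[g]]]
        perm = _perm_es(absr_p, len(present), n_perm, rng)
        if es >= 0:
            same = perm[perm >= 0]
            n_extreme = int((same >= es).sum())
        else:
            same = perm[perm < 0]
            n_extreme = int((same <= es).sum())
        p_nom = (1.0 + n_extreme) / (1.0 + same.size)
        mean_same = float(np.abs(same).mean()) if same.size else np.nan
        nes = es / mean_same if (mean_same and np.isfinite(mean_same)) else np.nan
        res = EnrichmentResult(name, es, nes, p_nom, np.nan, len(present),
                               leading, running if keep_running_sum else None)
        results.append(res)
        rows.append({"set_name": name, "size_used": len(present), "es": es,
                     "nes": nes, "p_nominal": p_nom,
                     "leading_edge": ",".join(leading)})
    if not rows:
        return pd.DataFrame(columns=["set_name", "size_used", "es", "nes",
                                     "p_nominal", "p_adjusted", "leading_edge"])
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.maximum(bh_adjust(table["p_nominal"].to_numpy()),
                                     table["p_nominal"].to_numpy())
    for res, padj in zip(results, table["p_adjusted"]):
        res.p_adjusted = float(padj)
    table.attrs["results"] = results
    return table.sort_values("p_nominal", kind="stable").reset_index(drop=True)


def overrepresentation_test(query, sets: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of a query gene list.

    For each set the p-value is P[overlap >= observed] drawing |query| genes
    from the universe; BH adjustment across sets. Query genes outside the
    universe are an error.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in uni]
    if outside:
        raise ValueError(f"query genes outside the universe: {outside[:10]}")
    M, n_query = len(universe), len(query)
    rows = []
    for name, members in sets.sets.items():
        in_uni = [g for g in dict.fromkeys(members) if g in uni]
        K = len(in_uni)
        overlap = len(set(in_uni) & set(query))
        if K == 0:
            p = 1.0
            fold = np.nan
        else:
            p = float(stats.hypergeom.sf(overlap - 1, M, K, n_query))
            expected = n_query * K / M
            fold = overlap / expected if expected > 0 else np.nan
        rows.append({"set_name": name, "set_size": K, "overlap": overlap,
                     "fold_enrichment": fold, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.maximum(bh_adjust(table["p"].to_numpy()),
                                     table["p"].to_numpy())
    return table.sort_values("p", kind="stable").reset_index(drop=True)
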