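"""Signature-gene extraction from encoder weights of selected hidden units.

For each clinically relevant hidden unit the top-k genes by (signed) encoder
weight are taken as candidate markers, after removing ribosomal genes so that
housekeeping translation machinery does not dominate the list; per-unit lists
are merged (union, first-seen order) into one signature, and intersections
between the positively and negatively cluster-associated unit classes are
tabulated.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dae import DAEModel

#: Ribosomal / mitoribosomal HGNC-style symbol patterns excluded by default.
DEFAULT_EXCLUSION_PATTERNS = (r"^RP[LS]\d", r"^MRP[LS]")
TOP_K = 200


@dataclass
class SignatureGeneList:
    """Ordered unique gene symbols with per-gene provenance and importance."""

    genes: list
    source_units: dict = field(default_factory=dict)  # gene -> list of unit indices
    weights: dict = field(default_factory=dict)       # gene -> list of weights
    importance: dict = field(default_factory=dict)    # gene -> real score

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene list contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "units": [",".join(f"H{u + 1}" for u in self.source_units.get(g, []))
                          for g in self.genes],
                "weights": [",".join(f"{w:.6g}" for w in self.weights.get(g, []))
                            for g in self.genes],
                "importance": [self.importance.get(g, np.nan) for g in self.genes],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_gmt_line(self, name: str = "SIGNATURE", description: str = "na") -> str:
        return "\t".join([name, description, *self.genes])


def top_weighted_genes(model: DAEModel, unit: int, k: int = TOP_K,
                       exclusion_patterns=DEFAULT_EXCLUSION_PATTERNS,
                       absolute: bool = False) -> list:
    """Top-k genes of one hidden unit by decreasing encoder weight.

    Genes matching any exclusion pattern are removed BEFORE ranking, so the
    returned list always holds k informative genes when enough remain. Ties
    at equal weight are broken by lexicographic gene symbol. With
    ``absolute=True`` ranking uses |weight| instead of the signed weight.
    """
    if not 0 <= unit < model.n_hidden:
        raise ValueError(f"unit {unit} out of range")
    if k < 1:
        raise ValueError("k must be >= 1")
    compiled = [re.compile(p) for p in exclusion_patterns]
    weights = model.W[unit]
    keep = [(g, w) for g, w in zip(model.gene_ids, weights)
            if not any(c.search(g) for c in compiled)]
    if k > len(keep):
        warnings.warn(f"requested k={k} but only {len(keep)} genes remain "
                      f"after exclusion; returning all")
        k = len(keep)
    key = (lambda gw: (-abs(gw[1]), gw[0])) if absolute else (lambda gw: (-gw[1], gw[0]))
    ranked = sorted(keep, key=key)
    return [g for g, _ in ranked[:k]]


def merge_signatures(lists, model: DAEModel | None = None, units=None) -> SignatureGeneList:
    """Union of per-unit gene lists, first-seen order, with provenance.

    ``lists`` is a sequence of gene lists; ``units`` optionally gives the
    hidden-unit index of each list and ``model`` supplies the weights for
    provenance.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("no gene lists to merge")
    if units is None:
        units = list(range(len(lists)))
    gene_index = {g: i for i, g in enumerate(model.gene_ids)} if model is not None else {}
    genes: list = []
    source_units: dict = {}
    weights: dict = {}
    for unit, genelist in zip(units, lists):
        for g in genelist:
            if g not in source_units:
                genes.append(g)
                source_units[g] = []
                weights[g] = []
            source_units[g].append(unit)
            if model is not None:
                if g not in gene_index:
                    raise ValueError(f"gene {g!r} not in model gene_ids")
                weights[g].append(float(model.W[unit, gene_index[g]]))
    return SignatureGeneList(genes, source_units, weights)


def class_intersections(pos_lists: dict, neg_lists: dict) -> dict:
    """Pairwise intersection sizes within and across unit classes.

    ``pos_lists`` / ``neg_lists`` map list names (e.g. "H36") to gene lists.
    Returns pairwise intersection sizes, the genes common to the union of
    each class, and the cross-class overlap gene list.
    """
    if not pos_lists or not neg_lists:
        raise ValueError("need at least one list per class")
    all_lists = {**{f"pos:{k}": set(v) for k, v in pos_lists.items()},
                 **{f"neg:{k}": set(v) for k, v in neg_lists.items()}}
    names = list(all_lists)
    pairwise = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            pairwise[(na, nb)] = len(all_lists[na] & all_lists[nb])
    pos_union = set().union(*(set(v) for v in pos_lists.values()))
    neg_union = set().union(*(set(v) for v in neg_lists.values()))
    cross = sorted(pos_union & neg_union)
    return {
        "pairwise_sizes": pairwise,
        "pos_union_size": len(pos_union),
        "neg_union_size": len(neg_union),
        "cross_class_overlap": cross,
        "cross_class_overlap_size": len(cross),
    }
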