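"""Selection and annotation of clinically relevant hidden units.

Hidden units are filtered by embedding variance, correlated (Spearman)
against the ordinal patient-cluster label and against continuous FEV1/FVC
traits, classified as positively or negatively cluster-associated, and the
embedding is hierarchically clustered to compare against known patient
groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .dae import Embedding

VARIANCE_THRESHOLD = 0.001
RHO_THRESHOLD = 0.65
#: Pairs of selected units correlating above this are flagged as redundant.
REDUNDANCY_RHO = 0.95


@dataclass
class HiddenUnitAnnotation:
    unit_index: int  # zero-based column of the embedding
    variance: float
    rho_tea: float
    selected: bool
    sign_class: str  # "positive" | "negative" | "none"
    rho_fev1fvc_pre: float = np.nan
    rho_fev1fvc_post: float = np.nan

    @property
    def name(self) -> str:
        return f"H{self.unit_index + 1}"


def filter_by_variance(E: Embedding, threshold: float = VARIANCE_THRESHOLD) -> list:
    """Indices of units whose population (1/N) variance is >= threshold.

    The removal condition is strictly ``variance < threshold``, so a unit
    sitting exactly on the threshold is retained. Order is preserved.
    """
    if len(E.sample_ids) == 0:
        raise ValueError("empty embedding")
    variances = E.values.var(axis=0, ddof=0)
    return [i for i, v in enumerate(variances) if v >= threshold]


def spearman(a, b) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant input has no rank correlation")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def select_hsig(E: Embedding, metadata: pd.DataFrame,
                rho_threshold: float = RHO_THRESHOLD,
                variance_threshold: float = VARIANCE_THRESHOLD) -> list:
    """Annotate every hidden unit; select those passing variance and |rho| cuts.

    A unit is selected when its embedding variance passes
    ``filter_by_variance`` AND |Spearman rho| against the ordinal cluster
    label exceeds ``rho_threshold``; its sign class follows the sign of rho.
    Every embedded sample must carry a cluster label.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = [s for s in E.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    tea = meta.loc[E.sample_ids, "tea_cluster"]
    if tea.isna().any():
        bad = [s for s, v in zip(E.sample_ids, tea) if pd.isna(v)]
        raise ValueError(f"samples without a TEA cluster label: {bad[:5]}")
    tea = tea.to_numpy(float)
    retained = set(filter_by_variance(E, variance_threshold))
    variances = E.values.var(axis=0, ddof=0)

    annotations = []
    for i in range(E.n_units):
        col = E.values[:, i]
        if np.all(col == col[0]):
            rho = 0.0
        else:
            rho = spearman(col, tea)
        selected = (i in retained) and (abs(rho) > rho_threshold)
        sign_class = "none"
        if selected:
            sign_class = "positive" if rho > 0 else "negative"
        annotations.append(
            HiddenUnitAnnotation(unit_index=i, variance=float(variances[i]),
                                 rho_tea=rho, selected=selected,
                                 sign_class=sign_class)
        )
    return annotations


def redundant_pairs(E: Embedding, annotations, rho: float = REDUNDANCY_RHO) -> list:
    """Pairs of selected units whose embeddings correlate above ``rho``.

    Reported so strongly redundant units can be collapsed by the analyst;
    no automatic collapsing is performed.
    """
    selected = [a.unit_index for a in annotations if a.selected]
    pairs = []
    for ii, i in enumerate(selected):
        for j in selected[ii + 1:]:
            r = spearman(E.values[:, i], E.values[:, j])
            if abs(r) > rho:
                pairs.append((i, j, r))
    return pairs


def correlate_with_traits(E: Embedding, metadata: pd.DataFrame,
                          traits=("fev1fvc_pre", "fev1fvc_post")) -> pd.DataFrame:
    """Per-unit Spearman correlation with each continuous trait.

    Samples with a missing trait value are skipped pairwise; fewer than 3
    complete pairs for a trait is an error.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    out = {}
    for trait in traits:
        vals = meta.loc[E.sample_ids, trait].to_numpy(float)
        ok = np.isfinite(vals)
        if ok.sum() < 3:
            raise ValueError(f"trait {trait!r} has fewer than 3 observed samples")
        out[f"rho_{trait}"] = [
            spearman(E.values[ok, i], vals[ok]) for i in range(E.n_units)
        ]
    return pd.DataFrame(out, index=[f"H{i + 1}" for i in range(E.n_units)])


def annotate_units(E: Embedding, metadata: pd.DataFrame,
                   rho_threshold: float = RHO_THRESHOLD,
                   variance_threshold: float = VARIANCE_THRESHOLD) -> pd.DataFrame:
    """Full annotation table: variance, cluster rho, trait rhos, selection."""
    annotations = select_hsig(E, metadata, rho_threshold, variance_threshold)
    traits = correlate_with_traits(E, metadata)
    table = pd.DataFrame(
        {
            "unit": [a.name for a in annotations],
            "variance": [a.variance for a in annotations],
            "rho_tea": [a.rho_tea for a in annotations],
            "rho_fev1fvc_pre": traits["rho_fev1fvc_pre"].to_numpy(),
            "rho_fev1fvc_post": traits["rho_fev1fvc_post"].to_numpy(),
            "selected": [a.selected for a in annotations],
            "sign_class": [a.sign_class for a in annotations],
        }
    )
    return table


# ---------------------------------------------------------------------------
# hierarchical clustering of the embedding
# ---------------------------------------------------------------------------

def hierarchical_cluster(E: Embedding, n_clusters: int,
                         metric: str = "euclidean", method: str = "average"):
    """Agglomerative clustering of samples in embedding space.

    Returns (labels, linkage_matrix): 1-based cluster labels per sample and
    the scipy linkage matrix of the merge tree.
    """
    n = len(E.sample_ids)
    if n_clusters > n:
        raise ValueError("n_clusters exceeds sample count")
    Z = hierarchy.linkage(E.values, method=method, metric=metric)
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node):
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{node.dist:.6g}"
        left = walk(node.get_left())
        right = walk(node.get_right())
        return f"({left},{right}):{node.dist:.6g}"

    return walk(tree) + ";"
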