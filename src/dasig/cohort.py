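"""Synthetic sputum-transcriptome cohort generator.

Emulates the statistical structure the analysis assumes: a genes x samples
expression matrix carrying a small number of coherent gene modules whose
per-sample activity changes monotonically across three patient clusters
(transcriptomic endotypes), an ordinal asthma-severity label driven by module
activity through an ordered-logit model, FEV1/FVC ratios in (0,1) produced by
a logistic squash of module activity, ribosomal decoy genes with no planted
signal, plus matching gene-set (GMT) and protein-interaction fixtures.

The planted ground truth is returned alongside the data so downstream stages
can be scored for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .de_network import PPINetwork

SEVERITY_LEVELS = ("control", "mild", "moderate", "severe")

#: Scale of the half-normal module loadings (expression units per activity unit).
#: At 1.5 the planted modules dominate the across-sample covariance the way
#: strongly co-regulated endotype modules dominate real sputum transcriptomes.
LOADING_SCALE = 1.5
#: Per-module weight of activity in the severity ordered-logit score.
SEVERITY_COEF = 1.0
#: Per-module weight of activity in the FEV1/FVC logit (sign flipped vs severity).
TRAIT_COEF = 0.4
#: FEV1/FVC logit intercepts (pre-, post-treatment); post sits slightly higher.
TRAIT_INTERCEPT_PRE = 1.0
TRAIT_INTERCEPT_POST = 1.3


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``module_effect_size`` is the separation of a module's mean activity
    between the two extreme clusters, in units of the per-sample activity
    noise SD (which is 1); ``noise_sd`` is the SD of the i.i.d. Gaussian
    expression noise added on top of baseline + module signal.
    """

    n_genes: int = 2000
    n_samples: int = 120
    n_modules: int = 3
    genes_per_module: int = 30
    n_clusters: int = 3
    severity_fractions: tuple = (0.2, 0.3, 0.2, 0.3)  # control, mild, moderate, severe
    module_effect_size: float = 3.0
    noise_sd: float = 1.0
    n_ribosome_decoys: int = 50
    trait_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_samples", "n_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid config: {name} must be positive")
        if self.n_modules < 0 or self.genes_per_module < 1:
            raise ValueError("invalid config: n_modules >= 0 and genes_per_module >= 1 required")
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise ValueError(
                "invalid config: n_modules * genes_per_module exceeds n_genes"
            )
        if self.n_ribosome_decoys < 0:
            raise ValueError("invalid config: n_ribosome_decoys must be non-negative")
        if self.n_modules * self.genes_per_module + self.n_ribosome_decoys > self.n_genes:
            raise ValueError("invalid config: modules plus decoys exceed n_genes")
        if len(self.severity_fractions) != len(SEVERITY_LEVELS):
            raise ValueError("invalid config: severity_fractions needs 4 entries")
        if any(f < 0 for f in self.severity_fractions):
            raise ValueError("invalid config: severity_fractions must be non-negative")
        if abs(sum(self.severity_fractions) - 1.0) > 1e-9:
            raise ValueError("invalid config: severity_fractions must sum to 1")
        if self.module_effect_size < 0 or self.noise_sd <= 0 or self.trait_noise_sd < 0:
            raise ValueError(
                "invalid config: module_effect_size >= 0, noise_sd > 0, trait_noise_sd >= 0"
            )


@dataclass
class PlantedStructure:
    """Ground truth of a generated cohort, used for parameter-recovery tests."""

    module_gene_indices: list = field(default_factory=list)  # list of index arrays
    module_activity: np.ndarray = None  # samples x modules
    module_loadings: list = field(default_factory=list)  # per-module loading vectors
    severity_logit_coefficients: np.ndarray = None
    trait_coefficients: np.ndarray = None
    ribosome_decoy_indices: np.ndarray = None
    gene_ids: list = field(default_factory=list)

    def module_gene_symbols(self, m: int) -> list:
        return [self.gene_ids[i] for i in self.module_gene_indices[m]]

    def all_module_gene_symbols(self) -> set:
        return {self.gene_ids[i] for idx in self.module_gene_indices for i in idx}


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-t))


def generate_cohort(config: CohortConfig):
    """Generate (ExpressionMatrix, metadata DataFrame, PlantedStructure).

    Expression = gene baseline + sum_m activity[s,m] * loading[g,m] + noise,
    clipped to be non-negative. Module activity means are linearly spaced
    across clusters 1..n_clusters (direction alternating per module), with
    unit-SD Gaussian per-sample wobble. Severity comes from an ordered-logit
    score on module activities with thresholds set at the configured class
    fractions; FEV1/FVC pre/post are logistic squashes of module activity
    plus trait noise. Identical seeds give bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S, M, C = config.n_genes, config.n_samples, config.n_modules, config.n_clusters

    # cluster labels: near-equal sizes, order randomized
    clusters = rng.permutation(np.arange(S) % C) + 1

    # module activity: cluster-mean ramp (alternating direction) + unit noise
    if C > 1:
        ramp = (clusters - 1) / (C - 1) - 0.5  # in [-0.5, 0.5]
    else:
        ramp = np.zeros(S)
    directions = np.array([1.0 if m % 2 == 0 else -1.0 for m in range(M)])
    activity = np.empty((S, M))
    for m in range(M):
        activity[:, m] = directions[m] * config.module_effect_size * ramp + rng.normal(0.0, 1.0, S)

    # gene identities: module members, ribosomal decoys, background
    perm = rng.permutation(G)
    module_idx = [np.sort(perm[m * config.genes_per_module:(m + 1) * config.genes_per_module])
                  for m in range(M)]
    n_mod_genes = M * config.genes_per_module
    decoy_idx = np.sort(perm[n_mod_genes:n_mod_genes + config.n_ribosome_decoys])
    gene_ids = [f"G{i:05d}" for i in range(G)]
    for m in range(M):
        for k, i in enumerate(module_idx[m]):
            gene_ids[i] = f"MOD{m + 1}_G{k:03d}"
    for k, i in enumerate(decoy_idx):
        prefix = "RPL" if k % 2 == 0 else "RPS"
        gene_ids[i] = f"{prefix}{k + 3}"

    # expression: baseline + module signal + noise, clipped at zero
    baseline = rng.normal(6.0, 1.0, G)
    loadings = [np.abs(rng.normal(0.0, LOADING_SCALE, config.genes_per_module))
                for _ in range(M)]
    V = np.tile(baseline[:, None], (1, S))
    for m in range(M):
        V[module_idx[m], :] += np.outer(loadings[m], activity[:, m])
    V += rng.normal(0.0, config.noise_sd, (G, S))
    np.clip(V, 0.0, None, out=V)

    # severity: ordered logit on module activity, cut at configured fractions
    sev_coefs = SEVERITY_COEF * directions
    score = activity @ sev_coefs + rng.logistic(0.0, 1.0, S)
    order = np.argsort(score, kind="stable")
    boundaries = np.cumsum(np.round(np.array(config.severity_fractions) * S).astype(int))
    boundaries[-1] = S
    severity = np.empty(S, dtype=object)
    start = 0
    for level, stop in zip(SEVERITY_LEVELS, boundaries):
        severity[order[start:stop]] = level
        start = stop

    # FEV1/FVC: logistic squash of module activity + trait noise, in (0,1)
    trait_coefs = -TRAIT_COEF * directions
    lin = activity @ trait_coefs
    fev_pre = _sigmoid(TRAIT_INTERCEPT_PRE + lin + rng.normal(0.0, config.trait_noise_sd, S))
    fev_post = _sigmoid(TRAIT_INTERCEPT_POST + lin + rng.normal(0.0, config.trait_noise_sd, S))

    sample_ids = [f"S{j:03d}" for j in range(S)]
    matrix = ExpressionMatrix(gene_ids, sample_ids, V)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "severity": severity,
            "tea_cluster": clusters,
            "fev1fvc_pre": fev_pre,
            "fev1fvc_post": fev_post,
        }
    )
    structure = PlantedStructure(
        module_gene_indices=module_idx,
        module_activity=activity,
        module_loadings=loadings,
        severity_logit_coefficients=sev_coefs,
        trait_coefficients=trait_coefs,
        ribosome_decoy_indices=decoy_idx,
        gene_ids=gene_ids,
    )
    return matrix, metadata, structure


def generate_gene_sets(structure: PlantedStructure, n_null_sets: int,
                       set_size: int, seed: int) -> dict:
    """One gene set per planted module (its exact members) plus random null sets.

    Returns a mapping set-name -> list of gene symbols; planted sets are named
    ``MODULE_<m>``, null sets ``NULL_<k>``.
    """
    n_genes = len(structure.gene_ids)
    if set_size > n_genes:
        raise ValueError("set_size exceeds number of genes")
    rng = np.random.default_rng(seed)
    sets = {}
    for m in range(len(structure.module_gene_indices)):
        sets[f"MODULE_{m + 1}"] = structure.module_gene_symbols(m)
    for k in range(n_null_sets):
        members = rng.choice(n_genes, size=set_size, replace=False)
        sets[f"NULL_{k + 1}"] = [structure.gene_ids[i] for i in np.sort(members)]
    return sets


def generate_ppi(structure: PlantedStructure, config: CohortConfig, seed: int,
                 p_module: float = 0.25, p_background: float = 0.01) -> PPINetwork:
    """Random PPI network in which planted module genes are hub-like.

    Within-module gene pairs are wired with probability ``p_module`` (plus a
    spanning path so each module is connected); all other pairs use the sparse
    background probability ``p_background``. With zero modules the result is a
    plain Erdos-Renyi graph at ``p_background``.
    """
    rng = np.random.default_rng(seed)
    genes = list(structure.gene_ids)
    n = len(genes)
    edges = set()

    module_sets = [np.asarray(idx) for idx in structure.module_gene_indices]
    in_module = np.zeros(n, dtype=bool)
    for idx in module_sets:
        in_module[idx] = True

    # dense wiring + spanning path within each module (keeps modules connected)
    for idx in module_sets:
        k = len(idx)
        for a in range(k - 1):
            edges.add((genes[idx[a]], genes[idx[a + 1]]))
        iu, ju = np.triu_indices(k, 1)
        hit = rng.random(iu.size) < p_module
        for a, b in zip(idx[iu[hit]], idx[ju[hit]]):
            edges.add((genes[a], genes[b]))

    # sparse background: draw the binomial edge count, then sample pairs
    n_pairs = n * (n - 1) // 2
    n_bg = rng.binomial(n_pairs, p_background)
    i_idx = rng.integers(0, n, size=int(2.2 * n_bg) + 10)
    j_idx = rng.integers(0, n, size=i_idx.size)
    taken = 0
    for a, b in zip(i_idx, j_idx):
        if taken >= n_bg:
            break
        if a == b:
            continue
        if in_module[a] and in_module[b]:
            continue  # module pairs already handled at p_module
        pair = (genes[a], genes[b]) if genes[a] < genes[b] else (genes[b], genes[a])
        if pair not in edges:
            edges.add(pair)
            taken += 1

    return PPINetwork.from_edges(genes, sorted(edges))
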