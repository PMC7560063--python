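"""End-to-end orchestration of the signature-discovery analysis.

Stages, in order: preprocess -> train/validate the autoencoder -> embed
non-control samples -> select clinically relevant hidden units -> gene-set
enrichment of their encoder weights -> extract and merge top-weighted genes
-> random-forest severity classification with a random-gene baseline ->
out-of-bag permutation importance and top-50 selection -> FEV1/FVC
regression -> differential expression and PPI-centrality comparison. Every
intermediate is persisted and checksummed into a run manifest; one global
seed deterministically derives a per-stage seed by stage-name hashing so any
stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import dae as dae_mod
from . import de_network, enrichment, latent, prediction, signature as sig_mod
from .io import read_metadata, write_metadata
from .matrix import ExpressionMatrix
from .preprocessing import preprocess

PACKAGE_VERSION = "0.1.0"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """All paths, hyperparameters and thresholds of one pipeline run."""

    expression: str = ""
    metadata: str = ""
    gene_sets: str = ""
    edges: str = ""
    output_dir: str = "dasig_output"

    dae: dae_mod.DAEParams = field(default_factory=dae_mod.DAEParams)
    skip_quantile: bool = False
    variance_threshold: float = latent.VARIANCE_THRESHOLD
    rho_threshold: float = latent.RHO_THRESHOLD
    top_k: int = sig_mod.TOP_K
    n_signature: int = 50
    alpha: float = 0.1
    n_folds: int = prediction.N_FOLDS
    n_repeats: int = prediction.N_REPEATS
    n_trees: int = prediction.N_TREES
    importance_trials: int = prediction.N_IMPORTANCE_TRIALS
    baseline_samplings: int = prediction.N_BASELINE_SAMPLINGS
    gsea_permutations: int = 1000
    holdout_repeats: int = 10
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        if not (0 < self.rho_threshold <= 1):
            raise ValueError("rho_threshold must lie in (0, 1]")
        if self.variance_threshold < 0:
            raise ValueError("variance_threshold must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("top_k", "n_signature", "n_folds", "n_repeats", "n_trees",
                     "importance_trials", "baseline_samplings",
                     "gsea_permutations", "holdout_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if check_paths:
            for name in ("expression", "metadata", "gene_sets", "edges"):
                p = getattr(self, name)
                if not p or not Path(p).exists():
                    raise FileNotFoundError(f"input file for {name!r} not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        dae_params = dae_mod.DAEParams(**raw.pop("dae", {}))
        return cls(dae=dae_params, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str = PACKAGE_VERSION
    stages: dict = field(default_factory=dict)  # stage -> {outputs: {path: sha}, seconds}

    def record(self, stage: str, outputs: list, seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_pipeline(config: PipelineConfig, log=print) -> RunManifest:
    """Execute every stage, persisting intermediates under the output dir."""
    config.validate(check_paths=True)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash())

    def _stage(name):
        log(f"[dasig] stage: {name}")
        return time.time()

    try:
        # -- load + preprocess --------------------------------------------
        t0 = _stage("preprocess")
        X_raw = ExpressionMatrix.read_tsv(config.expression)
        metadata = read_metadata(config.metadata)
        scaled = preprocess(X_raw, skip_quantile=config.skip_quantile)
        scaled_path = out / "expression_scaled.tsv"
        scaled.write_tsv(scaled_path)
        log(f"[dasig]   {scaled.n_genes} genes x {scaled.n_samples} samples scaled")
        manifest.record("preprocess", [scaled_path], time.time() - t0)

        # -- train + holdout validation -----------------------------------
        t0 = _stage("train")
        params = dae_mod.DAEParams(**{**asdict(config.dae),
                                      "seed": stage_seed(config.seed, "train")})
        model, trace = dae_mod.train(scaled, params)
        model_path = out / "dae_model.npz"
        model.save(model_path)
        trace_path = out / "training_trace.tsv"
        pd.DataFrame({"epoch": range(1, len(trace.train_loss) + 1),
                      "train_loss": trace.train_loss}).to_csv(
            trace_path, sep="\t", index=False)
        holdout = dae_mod.holdout_validate(scaled, params,
                                           n_repeats=config.holdout_repeats)
        holdout_path = out / "holdout_validation.tsv"
        holdout.to_csv(holdout_path, sep="\t", index=False)
        manifest.record("train", [model_path, trace_path, holdout_path],
                        time.time() - t0)

        # -- embed non-control samples -------------------------------------
        t0 = _stage("embed")
        meta_idx = metadata.set_index("sample_id")
        non_control = [s for s in scaled.sample_ids
                       if meta_idx.loc[s, "severity"] != "control"]
        emb = dae_mod.embed(model, scaled, non_control)
        emb_path = out / "embedding.tsv"
        emb.write_tsv(emb_path)
        log(f"[dasig]   embedded {len(non_control)} non-control samples")
        manifest.record("embed", [emb_path], time.time() - t0)

        # -- hidden-unit annotation + clustering ---------------------------
        t0 = _stage("annotate_units")
        annotation = latent.annotate_units(
            emb, metadata, rho_threshold=config.rho_threshold,
            variance_threshold=config.variance_threshold)
        ann_path = out / "hidden_unit_annotation.tsv"
        annotation.to_csv(ann_path, sep="\t", index=False)
        selected = annotation[annotation["selected"]]
        log(f"[dasig]   selected units: {', '.join(selected['unit']) or 'none'}")
        retained = latent.filter_by_variance(emb, config.variance_threshold)
        emb_rt = dae_mod.Embedding(emb.sample_ids, emb.values[:, retained])
        n_clust = int(meta_idx.loc[non_control, "tea_cluster"].nunique())
        labels, Z = latent.hierarchical_cluster(emb_rt, max(n_clust, 2))
        clust_path = out / "embedding_clusters.tsv"
        pd.DataFrame({"sample_id": emb.sample_ids, "cluster": labels}).to_csv(
            clust_path, sep="\t", index=False)
        tree_path = out / "embedding_tree.nwk"
        tree_path.write_text(latent.linkage_to_newick(Z, emb.sample_ids))
        manifest.record("annotate_units", [ann_path, clust_path, tree_path],
                        time.time() - t0)

        # -- enrichment of encoder weights ---------------------------------
        t0 = _stage("gsea")
        sets = enrichment.read_gmt(config.gene_sets)
        gsea_paths = []
        sel_units = [int(u[1:]) - 1 for u in selected["unit"]]
        for u in sel_units:
            stats_map = dict(zip(model.gene_ids, model.W[u]))
            res = enrichment.preranked_gsea(
                stats_map, sets, n_perm=config.gsea_permutations,
                seed=stage_seed(config.seed, f"gsea:{u}"))
            p = out / f"gsea_H{u + 1}.tsv"
            res.to_csv(p, sep="\t", index=False)
            gsea_paths.append(p)
        manifest.record("gsea", gsea_paths, time.time() - t0)

        # -- signature extraction ------------------------------------------
        t0 = _stage("signature")
        per_unit = {u: sig_mod.top_weighted_genes(model, u, k=config.top_k)
                    for u in sel_units}
        if not per_unit:
            raise RuntimeError("no hidden units selected; cannot build a signature")
        merged = sig_mod.merge_signatures(list(per_unit.values()), model=model,
                                          units=list(per_unit))
        sig_path = out / "signature.tsv"
        merged.write_tsv(sig_path)
        gmt_path = out / "signature.gmt"
        gmt_path.write_text(merged.to_gmt_line("DASIG_SIGNATURE") + "\n")
        sign_of = dict(zip(annotation["unit"], annotation["sign_class"]))
        pos = {f"H{u + 1}": g for u, g in per_unit.items()
               if sign_of[f"H{u + 1}"] == "positive"}
        neg = {f"H{u + 1}": g for u, g in per_unit.items()
               if sign_of[f"H{u + 1}"] == "negative"}
        inter_path = out / "class_intersections.json"
        if pos and neg:
            inter = sig_mod.class_intersections(pos, neg)
            inter_path.write_text(json.dumps(
                {"pairwise_sizes": {f"{a}|{b}": v for (a, b), v
                                    in inter["pairwise_sizes"].items()},
                 "pos_union_size": inter["pos_union_size"],
                 "neg_union_size": inter["neg_union_size"],
                 "cross_class_overlap_size": inter["cross_class_overlap_size"],
                 "cross_class_overlap": inter["cross_class_overlap"]}, indent=2))
        else:
            inter_path.write_text(json.dumps(
                {"note": "only one sign class present; no cross-class table"}))
        log(f"[dasig]   merged signature: {len(merged)} genes from "
            f"{len(per_unit)} units")
        manifest.record("signature", [sig_path, gmt_path, inter_path],
                        time.time() - t0)

        # -- severity prediction + importance ------------------------------
        t0 = _stage("predict_severity")
        ms_ids = [s for s in scaled.sample_ids
                  if meta_idx.loc[s, "severity"] in ("mild", "severe")]
        ms_labels = meta_idx.loc[ms_ids, "severity"].to_numpy()
        X_ms = scaled.subset_samples(ms_ids)
        X_sig = X_ms.subset_genes(merged.genes)
        cv = prediction.rf_severity_cv(
            X_sig, ms_labels, n_folds=config.n_folds, n_repeats=config.n_repeats,
            n_trees=config.n_trees, seed=stage_seed(config.seed, "rf"))
        base_mean, base_dist = prediction.random_gene_baseline(
            X_ms, ms_labels, n_genes=config.n_signature,
            n_samplings=config.baseline_samplings, n_folds=config.n_folds,
            n_trees=config.n_trees, seed=stage_seed(config.seed, "baseline"))
        imp = prediction.oob_permutation_importance(
            X_sig, ms_labels, n_trees=config.n_trees,
            n_trials=config.importance_trials,
            seed=stage_seed(config.seed, "importance"))
        imp_path = out / "importance.tsv"
        imp.to_csv(imp_path, sep="\t", index=False)
        top = prediction.select_top_features(imp, k=config.n_signature)
        top_path = out / "signature_top.tsv"
        top.write_tsv(top_path)
        cv_top = prediction.rf_severity_cv(
            X_ms.subset_genes(top.genes), ms_labels, n_folds=config.n_folds,
            n_repeats=config.n_repeats, n_trees=config.n_trees,
            seed=stage_seed(config.seed, "rf_top"))
        metrics = {
            "signature_auroc": cv.metric_value,
            "signature_top_auroc": cv_top.metric_value,
            "baseline_auroc_mean": base_mean,
            "baseline_auroc_sd": float(np.std(base_dist, ddof=1))
            if len(base_dist) > 1 else 0.0,
            "n_mild_severe_samples": len(ms_ids),
        }
        metrics_path = out / "severity_metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2))
        log(f"[dasig]   signature AUROC {cv.metric_value:.3f} "
            f"(top-{config.n_signature}: {cv_top.metric_value:.3f}) "
            f"vs baseline {base_mean:.3f}")
        manifest.record("predict_severity",
                        [imp_path, top_path, metrics_path], time.time() - t0)

        # -- trait regression ----------------------------------------------
        t0 = _stage("predict_trait")
        trait_metrics = {}
        X_top_all = scaled.subset_samples(non_control).subset_genes(top.genes)
        for trait in ("fev1fvc_pre", "fev1fvc_post"):
            yv = meta_idx.loc[non_control, trait].to_numpy(float)
            ok = np.isfinite(yv)
            Xt = X_top_all.subset_samples([s for s, m in zip(non_control, ok) if m])
            for method in ("svr", "lasso"):
                res = prediction.regress_trait(
                    Xt, yv[ok], method=method, n_folds=config.n_folds,
                    seed=stage_seed(config.seed, f"trait:{trait}:{method}"))
                trait_metrics[f"{trait}_{method}"] = res.metrics
        trait_path = out / "trait_metrics.json"
        trait_path.write_text(json.dumps(trait_metrics, indent=2))
        manifest.record("predict_trait", [trait_path], time.time() - t0)

        # -- differential expression ---------------------------------------
        t0 = _stage("de")
        de = de_network.differential_expression(X_ms, ms_labels, alpha=config.alpha)
        de_path = out / "differential_expression.tsv"
        de.to_csv(de_path, sep="\t", index=False)
        degs = list(de.loc[de["significant"], "gene"])
        log(f"[dasig]   {len(degs)} significant DEGs at BH {config.alpha}")
        manifest.record("de", [de_path], time.time() - t0)

        # -- network comparison --------------------------------------------
        t0 = _stage("network")
        net = de_network.load_edges(config.edges)
        net_path = out / "network_comparison.json"
        if degs and set(top.genes) & set(net.nodes) and set(degs) & set(net.nodes):
            shell = de_network.first_shell(net, list(dict.fromkeys(top.genes + degs)))
            report = de_network.compare_gene_lists_centrality(shell, top.genes, degs)
            net_path.write_text(json.dumps(
                {"degree_p_greater": report["degree"]["p_greater"],
                 "betweenness_p_greater": report["betweenness"]["p_greater"],
                 "degree_mean_signature": report["degree"]["mean_a"],
                 "degree_mean_degs": report["degree"]["mean_b"],
                 "n_signature_in_network": len(report["genes_used_a"]),
                 "n_degs_in_network": len(report["genes_used_b"])}, indent=2))
        else:
            net_path.write_text(json.dumps(
                {"note": "comparison skipped: no DEGs or no network overlap"}))
        manifest.record("network", [net_path], time.time() - t0)
    except Exception as err:
        failed = len(manifest.stages)
        raise RuntimeError(
            f"pipeline failed at stage {failed + 1} "
            f"(after {list(manifest.stages)}): {err}"
        ) from err

    manifest.write(out / "manifest.json")
    return manifest


def make_fixture(output_dir, seed: int = 0,
                 config: cohort_mod.CohortConfig | None = None) -> dict:
    """Write the standard synthetic cohort bundle (2,000 genes x 120 samples).

    Emits expression TSV, metadata TSV, GMT gene sets (planted modules + null
    sets), a PPI edge list, and a summary JSON; returns the file paths.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = cohort_mod.CohortConfig(seed=seed)
    X, metadata, structure = cohort_mod.generate_cohort(config)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "edges": out / "ppi_edges.tsv",
        "summary": out / "cohort_summary.json",
    }
    X.write_tsv(paths["expression"])
    write_metadata(metadata, paths["metadata"])
    sets = cohort_mod.generate_gene_sets(structure, n_null_sets=20,
                                         set_size=config.genes_per_module,
                                         seed=stage_seed(seed, "gene_sets"))
    enrichment.GeneSetCollection(sets, source="dasig synthetic cohort").write_gmt(
        paths["gene_sets"])
    net = cohort_mod.generate_ppi(structure, config,
                                  seed=stage_seed(seed, "ppi"))
    net.write_tsv(paths["edges"])
    summary = {
        "n_genes": config.n_genes,
        "n_samples": config.n_samples,
        "n_modules": config.n_modules,
        "genes_per_module": config.genes_per_module,
        "module_effect_size": config.module_effect_size,
        "severity_counts": metadata["severity"].value_counts().to_dict(),
        "seed": seed,
    }
    Path(paths["summary"]).write_text(json.dumps(summary, indent=2))
    return {k: str(v) for k, v in paths.items()}
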