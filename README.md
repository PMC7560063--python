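# dasig

Denoising-autoencoder gene-signature discovery for asthma severity from
sputum transcriptomes.

Asthma is heterogeneous: patient subgroups (transcriptomic endotypes) differ
in molecular mechanism, and severity does not map onto any single
differentially expressed gene. `dasig` addresses this by learning an
unsupervised low-dimensional representation of bulk sputum expression with a
one-layer **tied-weight denoising autoencoder**,

```
y = sigmoid(W x* + b),   z = sigmoid(Wᵀ y + b′),
L = Σⱼ −xⱼ log zⱼ − (1−xⱼ) log(1−zⱼ),
```

trained by SGD with the closed-form gradients of `L` (x* is the input with
entries randomly masked to zero). Hidden units whose activations track
clinical endotype clusters are selected (embedding variance ≥ 0.001,
|Spearman ρ| > 0.65), annotated by pre-ranked GSEA on their encoder-weight
rows, and mined for signature genes: the top-200 weights per unit
(ribosomal genes excluded) are merged, pruned to 50 genes by random-forest
out-of-bag permutation importance, and evaluated by mild-vs-severe AUROC
against random-gene panels, FEV1/FVC regression (SVR/LASSO), and
PPI-network centrality against plain DEGs.

The original patient cohort is not publicly deposited, so the package ships
a first-class **synthetic cohort generator** that plants the structure the
analysis assumes — co-regulated gene modules ramping across three patient
clusters, an ordered-logit severity label, logistic-squashed FEV1/FVC
ratios, ribosomal decoy genes, matching GMT gene sets and a hub-structured
PPI network — with full ground truth for parameter-recovery benchmarking.
It is intended for methods developers and computational biologists who want
a tested, configuration-driven reference implementation of this workflow.

## Worked example

```python
import dasig

X, metadata, truth = dasig.generate_cohort(dasig.CohortConfig(seed=42))
scaled = dasig.preprocess(X)                       # quantile + min-max
model, trace = dasig.train(scaled, dasig.DAEParams(
    n_hidden=50, epochs=30, learning_rate=0.01, seed=42))
embedding = dasig.embed(model, scaled)
selected = [a.unit_index for a in dasig.select_hsig(embedding, metadata)
            if a.selected]
merged = dasig.merge_signatures(
    [dasig.top_weighted_genes(model, u, k=200) for u in selected],
    model=model, units=selected)
```

Running `examples/05_signature_and_severity.py`, which continues this chain
through importance pruning and classification, prints:

```
merged signature from 28 units: 1889 genes
planted-module genes in the top 50: 50 / 50
signature AUROC 0.965 vs random-gene baseline 0.787
```

All 50 signature genes land in the planted modules, and the signature panel
separates mild from severe far better than random 50-gene panels — the
contrast the method exists to produce. `examples/` holds one short script
per capability (cohort generation, training, unit selection, enrichment,
signature/severity, trait regression + network comparison); each prints its
numbers with a note on what they mean.

A thin CLI covers the same ground for shell use
(`dasig fixtures|preprocess|train|embed|annotate-units|gsea|signature|
predict-severity|predict-trait|de|network|run-all`), with `run-all` driven
by a YAML configuration.

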