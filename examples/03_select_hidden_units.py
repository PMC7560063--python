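"""Select clinically relevant hidden units and cluster the embedding.

Units are kept when their embedding variance reaches 0.001 and |Spearman|
with the ordinal patient-cluster label exceeds 0.65; hierarchical clustering
of the retained embedding is compared with the planted clusters.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import dasig

X, metadata, truth = dasig.generate_cohort(dasig.CohortConfig(seed=42))
scaled = dasig.preprocess(X)
model, _ = dasig.train(scaled, dasig.DAEParams(
    n_hidden=50, epochs=30, learning_rate=0.01, seed=42))
embedding = dasig.embed(model, scaled)

table = dasig.annotate_units(embedding, metadata)
selected = table[table["selected"]]
print(f"{len(selected)} of {len(table)} units selected")
print(selected.head(8).round(3).to_string(index=False))

retained = dasig.filter_by_variance(embedding)
emb = dasig.Embedding(embedding.sample_ids, embedding.values[:, retained])
labels, _ = dasig.hierarchical_cluster(emb, 3)
raw = dasig.Embedding(scaled.sample_ids, scaled.values.T)
labels_raw, _ = dasig.hierarchical_cluster(raw, 3)
cl = metadata["tea_cluster"].to_numpy()
print(f"ARI vs planted clusters: embedding {adjusted_rand_score(cl, labels):.3f}, "
      f"raw expression {adjusted_rand_score(cl, labels_raw):.3f}")
# Units of both sign classes appear because the sigmoid can encode a module
# factor with either orientation. Single seeds vary: averaged over many
# cohorts the embedding ARI exceeds the raw-expression ARI (the acceptance
# suite checks the 20-seed mean), but either can win on one draw.
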