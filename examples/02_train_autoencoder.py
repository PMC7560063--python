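"""Preprocess a cohort and train the tied-weight denoising autoencoder.

Expression is quantile-normalized across samples and min-max scaled per
sample to [0,1]; the autoencoder then learns a 50-unit sigmoid embedding by
SGD on the cross-entropy reconstruction loss with masking corruption.
"""

import dasig

X, metadata, _ = dasig.generate_cohort(dasig.CohortConfig(seed=42))
scaled = dasig.preprocess(X)
print(f"scaled matrix range: [{scaled.values.min()}, {scaled.values.max()}]")

params = dasig.DAEParams(n_hidden=50, epochs=30, learning_rate=0.01,
                         corruption_rate=0.001, seed=42)
model, trace = dasig.train(scaled, params)
print(f"training loss: epoch 1 = {trace.train_loss[0]:.1f}, "
      f"epoch {params.epochs} = {trace.train_loss[-1]:.1f}")

holdout = dasig.holdout_validate(scaled, params, n_repeats=3)
print(holdout.round(2).to_string(index=False))
ratio = holdout["test_loss"].mean() / holdout["train_loss"].mean()
print(f"test/train loss ratio = {ratio:.3f}  (close to 1: no gross overfitting)")
# The loss is summed over genes, so its floor is the entropy of the scaled
# data itself; what matters is the decrease and the train/test agreement.
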