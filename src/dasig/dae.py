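"""One-layer tied-weight denoising autoencoder for expression matrices.

The model maps a corrupted sample vector x* (genes, scaled to [0,1]) to a
hidden representation y = sigmoid(W x* + b) and reconstructs
z = sigmoid(W^T y + b'); the decoder weight is the transpose of the encoder
weight by construction, so the only parameters are W (n_hidden x n_genes),
b (n_hidden) and b' (n_genes). Training minimizes the elementwise
cross-entropy reconstruction loss

    L = sum_j [ -x_j log z_j - (1 - x_j) log(1 - z_j) ]

by stochastic gradient descent using the closed-form gradients

    dL/dW_ij = (z_j - x_j) y_i + [ sum_k (z_k - x_k) W_ik ] y_i (1 - y_i) x*_j
    dL/db_i  = [ sum_k (z_k - x_k) W_ik ] y_i (1 - y_i)
    dL/db'_j = z_j - x_j

Corruption masks each input entry to zero independently with the configured
rate, freshly drawn at every sample visit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

_EPS = 1e-12
MODEL_FORMAT_VERSION = 1


@dataclass
class DAEParams:
    """Training hyperparameters (defaults are the reference settings:
    50 hidden units, 100 epochs, learning rate 0.1, corruption rate 0.001)."""

    n_hidden: int = 50
    epochs: int = 100
    learning_rate: float = 0.1
    corruption_rate: float = 0.001
    seed: int = 0
    batch_mode: str = "per_sample"  # or "full_batch"

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must lie in [0, 1]")
        if self.batch_mode not in ("per_sample", "full_batch"):
            raise ValueError("batch_mode must be 'per_sample' or 'full_batch'")


@dataclass
class DAEModel:
    """Trained (or initialized) autoencoder; decoder weight is W.T, never stored."""

    W: np.ndarray  # n_hidden x n_genes
    b: np.ndarray  # n_hidden
    b_prime: np.ndarray  # n_genes
    params: DAEParams
    gene_ids: list

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.b_prime = np.asarray(self.b_prime, dtype=float)
        h, g = self.W.shape
        if self.b.shape != (h,) or self.b_prime.shape != (g,):
            raise ValueError("bias shapes inconsistent with W")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length inconsistent with W")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_genes(self) -> int:
        return self.W.shape[1]

    # -- serialization (flat npz archive with a format-version field) ------
    def save(self, path) -> None:
        np.savez_compressed(
            path,
            format_version=MODEL_FORMAT_VERSION,
            W=self.W,
            b=self.b,
            b_prime=self.b_prime,
            params=json.dumps(asdict(self.params)),
            gene_ids=np.asarray(self.gene_ids, dtype=object),
        )

    @classmethod
    def load(cls, path) -> "DAEModel":
        with np.load(path, allow_pickle=True) as arc:
            version = int(arc["format_version"])
            if version != MODEL_FORMAT_VERSION:
                raise ValueError(f"unsupported model format version {version}")
            params = DAEParams(**json.loads(str(arc["params"])))
            return cls(arc["W"], arc["b"], arc["b_prime"], params,
                       [str(g) for g in arc["gene_ids"]])


@dataclass
class TrainingTrace:
    """Per-epoch mean training loss (and optional validation loss)."""

    train_loss: list = field(default_factory=list)
    validation_loss: list = field(default_factory=list)


@dataclass
class Embedding:
    """Samples x hidden-units matrix of sigmoid activations, all in (0,1)."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count must match sample_ids")

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"H{i + 1}" for i in range(self.n_units)]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)

    def write_tsv(self, path) -> None:
        self.to_frame().rename_axis("sample").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def sigmoid(t):
    """Numerically stable logistic function."""
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def corrupt(x, rate: float, rng) -> np.ndarray:
    """Mask each entry of ``x`` to zero independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("corruption rate must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    if rate == 0.0:
        return x.copy()
    mask = rng.random(x.shape) >= rate
    return x * mask


def encode(model: DAEModel, x_star) -> np.ndarray:
    """Hidden activation y = sigmoid(W x* + b)."""
    x_star = np.asarray(x_star, dtype=float)
    if x_star.shape[-1] != model.n_genes:
        raise ValueError(f"expected {model.n_genes} genes, got {x_star.shape[-1]}")
    return sigmoid(x_star @ model.W.T + model.b)


def decode(model: DAEModel, y) -> np.ndarray:
    """Reconstruction z = sigmoid(W^T y + b')."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != model.n_hidden:
        raise ValueError(f"expected {model.n_hidden} hidden values, got {y.shape[-1]}")
    return sigmoid(y @ model.W + model.b_prime)


def cross_entropy_loss(x, z) -> float:
    """Elementwise cross-entropy between target x in [0,1] and reconstruction z.

    z is clamped to [1e-12, 1 - 1e-12] so exact 0/1 reconstructions never
    produce log(0).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("x and z must have the same shape")
    zc = np.clip(z, _EPS, 1.0 - _EPS)
    return float(np.sum(-x * np.log(zc) - (1.0 - x) * np.log(1.0 - zc)))


def analytic_gradients(model: DAEModel, x, x_star):
    """Closed-form loss gradients (dW, db, db_prime) at one sample.

    ``x`` is the clean target, ``x_star`` the corrupted input actually fed to
    the encoder; y and z are recomputed internally from ``x_star``.
    """
    x = np.asarray(x, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    if x.shape != (model.n_genes,) or x_star.shape != (model.n_genes,):
        raise ValueError("x and x_star must be vectors of length n_genes")
    y = encode(model, x_star)
    z = decode(model, y)
    delta = z - x  # n_genes
    back = model.W @ delta  # n_hidden: sum_k delta_k W_ik
    gate = back * y * (1.0 - y)  # n_hidden
    dW = np.outer(y, delta) + np.outer(gate, x_star)
    db = gate
    db_prime = delta
    return dW, db, db_prime


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def _check_scaled(V: np.ndarray) -> None:
    if V.min() < -1e-9 or V.max() > 1.0 + 1e-9:
        raise ValueError("input matrix must be scaled to [0,1] (run preprocessing)")

def initialize_model(n_genes: int, params: DAEParams, gene_ids, rng,
                     gene_means=None) -> DAEModel:
    """Uniform +/- 4*sqrt(6/(n_genes+n_hidden)) weight init.

    The encoder bias starts at zero; the decoder bias starts at the logit of
    each gene's training mean when ``gene_means`` is given, so the initial
    reconstruction already matches the per-gene marginals. Without that
    offset the early reconstruction error is shared across genes and the
    resulting row-coherent weight updates drive every hidden unit deep into
    sigmoid saturation before any structure is learned.
    """
    bound = 4.0 * np.sqrt(6.0 / (n_genes + params.n_hidden))
    W = rng.uniform(-bound, bound, (params.n_hidden, n_genes))
    if gene_means is None:
        b_prime = np.zeros(n_genes)
    else:
        m = np.clip(np.asarray(gene_means, dtype=float), 1e-3, 1.0 - 1e-3)
        b_prime = np.log(m / (1.0 - m))
    return DAEModel(W, np.zeros(params.n_hidden), b_prime, params, list(gene_ids))


def train(X: ExpressionMatrix, params: DAEParams,
          rng: np.random.Generator | None = None):
    """Train on all samples (columns) of a [0,1]-scaled matrix.

    Per-sample mode performs one SGD step per sample visit with the samples
    reshuffled each epoch; full-batch mode averages the per-sample gradients
    and takes one step per epoch. Fresh corruption is drawn at every visit.
    The trace records the per-epoch mean training loss (computed at visit
    time against the clean target). Deterministic under ``params.seed``.
    """
    if X.n_samples < 2:
        raise ValueError("training needs >= 2 samples")
    _check_scaled(X.values)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    model = initialize_model(X.n_genes, params, X.gene_ids, rng,
                             gene_means=X.values.mean(axis=1))
    trace = TrainingTrace()
    data = X.values.T  # samples x genes
    lr = params.learning_rate
    for _ in range(params.epochs):
        order = rng.permutation(X.n_samples)
        losses = np.empty(X.n_samples)
        if params.batch_mode == "per_sample":
            for pos, s in enumerate(order):
                x = data[s]
                x_star = corrupt(x, params.corruption_rate, rng)
                y = encode(model, x_star)
                z = decode(model, y)
                losses[pos] = cross_entropy_loss(x, z)
                delta = z - x
                gate = (model.W @ delta) * y * (1.0 - y)
                model.W -= lr * (np.outer(y, delta) + np.outer(gate, x_star))
                model.b -= lr * gate
                model.b_prime -= lr * delta
        else:  # full_batch: average gradients over all samples, one step
            Xc = np.stack([corrupt(data[s], params.corruption_rate, rng) for s in order])
            Y = encode(model, Xc)
            Z = decode(model, Y)
            Xo = data[order]
            Zc = np.clip(Z, _EPS, 1.0 - _EPS)
            losses = np.sum(-Xo * np.log(Zc) - (1 - Xo) * np.log(1 - Zc), axis=1)
            delta = Z - Xo
            gate = (delta @ model.W.T) * Y * (1.0 - Y)
            n = X.n_samples
            model.W -= lr * (Y.T @ delta + gate.T @ Xc) / n
            model.b -= lr * gate.mean(axis=0)
            model.b_prime -= lr * delta.mean(axis=0)
        trace.train_loss.append(float(losses.mean()))
    return model, trace


def reconstruction_loss(model: DAEModel, X: ExpressionMatrix) -> float:
    """Mean per-sample cross-entropy of the clean (uncorrupted) reconstruction."""
    data = X.values.T
    Z = decode(model, encode(model, data))
    Zc = np.clip(Z, _EPS, 1.0 - _EPS)
    per_sample = np.sum(-data * np.log(Zc) - (1 - data) * np.log(1 - Zc), axis=1)
    return float(per_sample.mean())


def holdout_validate(X: ExpressionMatrix, params: DAEParams,
                     n_repeats: int = 10, test_fraction: float = 0.1) -> pd.DataFrame:
    """Repeated random 90/10 hold-out: train on the rest, evaluate both sides.

    Each repeat draws an independent split (under ``params.seed``), trains a
    fresh model on the training samples and reports the mean reconstruction
    loss on the training and held-out samples.
    """
    n_test = int(round(X.n_samples * test_fraction))
    if n_test < 1 or n_test >= X.n_samples:
        raise ValueError("test_fraction leaves an empty train or test split")
    rng = np.random.default_rng(params.seed)
    rows = []
    for rep in range(n_repeats):
        perm = rng.permutation(X.n_samples)
        test_ids = [X.sample_ids[j] for j in perm[:n_test]]
        train_ids = [X.sample_ids[j] for j in perm[n_test:]]
        model, _ = train(X.subset_samples(train_ids), params, rng=rng)
        rows.append(
            {
                "repeat": rep,
                "train_loss": reconstruction_loss(model, X.subset_samples(train_ids)),
                "test_loss": reconstruction_loss(model, X.subset_samples(test_ids)),
            }
        )
    return pd.DataFrame(rows)


def grid_search(X: ExpressionMatrix, hidden_grid, epoch_grid,
                base: DAEParams, n_repeats: int = 3,
                test_fraction: float = 0.1) -> pd.DataFrame:
    """Mean hold-out test loss over the (n_hidden x epochs) hyperparameter grid."""
    hidden_grid = list(hidden_grid)
    epoch_grid = list(epoch_grid)
    if not hidden_grid or not epoch_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    rows = []
    for h in hidden_grid:
        for e in epoch_grid:
            params = DAEParams(n_hidden=h, epochs=e,
                               learning_rate=base.learning_rate,
                               corruption_rate=base.corruption_rate,
                               seed=base.seed, batch_mode=base.batch_mode)
            res = holdout_validate(X, params, n_repeats=n_repeats,
                                   test_fraction=test_fraction)
            rows.append({"n_hidden": h, "epochs": e,
                         "mean_train_loss": float(res["train_loss"].mean()),
                         "mean_test_loss": float(res["test_loss"].mean())})
    return pd.DataFrame(rows)


def embed(model: DAEModel, X: ExpressionMatrix, include_samples=None) -> Embedding:
    """Project samples into the hidden space using UNcorrupted inputs."""
    if list(X.gene_ids) != list(model.gene_ids):
        raise ValueError("matrix gene order does not match the model")
    if include_samples is None:
        include_samples = list(X.sample_ids)
    sub = X.subset_samples(list(include_samples))
    Y = encode(model, sub.values.T)
    return Embedding(list(include_samples), Y)
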