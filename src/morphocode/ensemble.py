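"""Stacked-generalization ensembles, majority voting, uncertainty metrics.

Several base CNN decoders are trained on the same data with different random
initializations; their probabilistic predictions on the training set are
concatenated into a new feature set on which a meta-classifier (logistic
regression by default, optionally a small feedforward network) is trained.
Majority voting instead aggregates the decoder's predictions across several
replicate patterns of the same character.  Uncertainty is summarized by the
negative log likelihood, the mean squared error of the probability vectors,
and the top-1 / top-5 error rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoder import (
    Dense,
    DecoderModel,
    DecoderSpec,
    ReLU,
    Sequential,
    predict_proba,
    train_decoder,
)

__all__ = [
    "StackDataset",
    "EnsembleModel",
    "UncertaintyReport",
    "train_bases",
    "make_stack_dataset",
    "train_stacker",
    "ensemble_predict_proba",
    "majority_vote",
    "uncertainty",
]

#: probability floor used inside the log likelihood
NLL_FLOOR = 1e-12


def train_bases(train_set, spec: DecoderSpec, m_models: int = 5, seeds=None):
    """Train ``m_models`` independently initialized decoders on the same data."""
    if m_models < 2:
        raise ValueError("an ensemble needs at least 2 base models")
    if seeds is None:
        seeds = list(range(m_models))
    seeds = list(seeds)
    if len(seeds) != m_models or len(set(seeds)) != m_models:
        raise ValueError("need exactly m_models distinct seeds")
    return [train_decoder(train_set, spec, s) for s in seeds]


@dataclass
class StackDataset:
    """Concatenated base-model probability vectors with the original labels."""

    features: np.ndarray  # (n, M * n_classes)
    labels: np.ndarray
    n_classes: int
    n_bases: int


def make_stack_dataset(bases, dataset, combine: str = "concat") -> StackDataset:
    """Stack features: per-model probability blocks concatenated (default)
    or averaged into a single block (``combine='average'``)."""
    ncs = {b.spec.n_classes for b in bases}
    if len(ncs) != 1:
        raise ValueError("base models disagree on the number of classes")
    (nc,) = ncs
    if nc != dataset.n_classes:
        raise ValueError("base models and dataset disagree on the number of classes")
    probs = [predict_proba(b, dataset.images) for b in bases]
    if combine == "concat":
        feats = np.concatenate(probs, axis=1)
    elif combine == "average":
        feats = np.mean(probs, axis=0)
    else:
        raise ValueError("combine must be 'concat' or 'average'")
    return StackDataset(
        features=feats, labels=dataset.labels, n_classes=nc, n_bases=len(bases)
    )


@dataclass
class EnsembleModel:
    net: Sequential
    n_classes: int
    n_bases: int
    architecture: str
    bases: list | None = None

    def predict_proba_from_features(self, features: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(features.astype(np.float32))


def train_stacker(
    stack: StackDataset,
    architecture: str = "logistic",
    hidden: tuple[int, ...] = (),
    rng_seed: int = 0,
    learning_rate: float = 1e-4,
    batch_size: int = 32,
    max_epochs: int = 2000,
    patience: int = 5,
    min_delta: float = 1e-4,
    bases=None,
) -> EnsembleModel:
    """Train the meta-classifier on the stacked probability features.

    ``architecture='logistic'`` is a softmax regression; ``'mlp'`` inserts
    ReLU hidden layers of the given widths.  Glorot-uniform initialization,
    categorical cross-entropy, Adam (lr 1e-4), early stopping with patience 5
    and minimum improvement 1e-4.
    """
    if len(stack.labels) == 0:
        raise ValueError("empty stack dataset")
    rng = np.random.default_rng(rng_seed)
    layers = []
    n_in = stack.features.shape[1]
    widths = tuple(hidden) if architecture == "mlp" else ()
    for w in widths:
        layers += [Dense(n_in, w, rng, init="glorot_uniform"), ReLU()]
        n_in = w
    layers.append(Dense(n_in, stack.n_classes, rng, init="glorot_uniform"))
    net = Sequential(layers)
    net.fit(
        stack.features,
        stack.labels,
        n_classes=stack.n_classes,
        rng=rng,
        lr=learning_rate,
        batch_size=batch_size,
        max_epochs=max_epochs,
        patience=patience,
        min_delta=min_delta,
        val_fraction=0.1,
    )
    return EnsembleModel(
        net=net,
        n_classes=stack.n_classes,
        n_bases=stack.n_bases,
        architecture=architecture if not widths else f"mlp{widths}",
        bases=bases,
    )


def ensemble_predict_proba(model: EnsembleModel, images: np.ndarray) -> np.ndarray:
    """End-to-end ensemble prediction (bases must be attached)."""
    if not model.bases:
        raise ValueError("ensemble has no attached base models")
    feats = np.concatenate([predict_proba(b, images) for b in model.bases], axis=1)
    return model.predict_proba_from_features(feats)


def majority_vote(labels, probabilities=None) -> int:
    """Modal label over ballots; ties broken by the highest summed probability
    across ballots, then by the lowest class index."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("majority_vote needs at least one ballot")
    counts = np.bincount(labels)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) == 1 or probabilities is None:
        return int(tied[0])
    probabilities = np.asarray(probabilities)
    summed = probabilities.sum(axis=0)
    best = tied[np.argmax(summed[tied])]
    return int(best)


@dataclass
class UncertaintyReport:
    nll: float
    mse: float
    top1_error: float
    top5_error: float

    def to_dict(self) -> dict:
        return {
            "nll": self.nll,
            "mse": self.mse,
            "top1_error": self.top1_error,
            "top5_error": self.top5_error,
        }


def uncertainty(probabilities: np.ndarray, labels: np.ndarray) -> UncertaintyReport:
    """Uncertainty metrics over M data points and N classes.

    nll  = -(1/M) sum_j sum_i y_ij ln(p_ij)          (natural log, p floored)
    mse  =  (1/(M N)) sum_j sum_i (y_ij - p_ij)^2
    topK = fraction of points whose true class is not among the K most
           probable predictions (ranking ties resolved toward lower index).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.ndim != 2 or len(p) != len(y):
        raise ValueError("probabilities must be (M, N) matching labels")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    m, n = p.shape
    p_true = p[np.arange(m), y]
    nll = float(-np.mean(np.log(np.clip(p_true, NLL_FLOOR, 1.0))))
    onehot = np.zeros_like(p)
    onehot[np.arange(m), y] = 1.0
    mse = float(np.sum((onehot - p) ** 2) / (m * n))
    # stable rank: sort by descending probability, lower index wins ties
    order = np.lexsort((np.arange(n)[None, :].repeat(m, 0), -p), axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(m)[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    true_rank = ranks[np.arange(m), y]
    top1 = float(np.mean(true_rank >= 1))
    top5 = float(np.mean(true_rank >= 5))
    return UncertaintyReport(nll=nll, mse=mse, top1_error=top1, top5_error=top5)
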