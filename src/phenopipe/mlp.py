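"""Per-indicator sentence classifiers: balanced dataset construction and a
small two-layer perceptron trained with momentum SGD.

One classifier is trained per indicator category to separate sentence
embeddings affirmed in that category from embeddings of sentences outside it.
The network is `dim -> 100 -> 2`: a fully connected layer, ReLU, a second
fully connected layer, and softmax over the two logits; training minimizes
cross-entropy with mini-batch stochastic gradient descent (learning rate
0.001, momentum 0.9) for 10 epochs.  These hyperparameters are the pipeline's
defaults; the implementation is plain NumPy and exactly reproducible under a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .tagger import AFFIRMED, TaggedSentence

__all__ = [
    "TrainConfig",
    "MLPModel",
    "SentenceDataset",
    "build_sentence_dataset",
    "train_mlp",
    "predict_proba",
    "evaluate_sentence_classifier",
    "save_model",
    "load_model",
]


@dataclass
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    hidden: int = 100
    seed: int = 0


@dataclass
class MLPModel:
    """Weights of one trained sentence classifier.

    ``forward`` computes ``softmax(W2 @ relu(W1 @ x + b1) + b2)``; the
    positive class is index 1.
    """

    W1: np.ndarray  # (dim, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden, 2)
    b2: np.ndarray  # (2,)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    loss_history: list = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.W1.shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (n, 2); rows sum to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.dim:
            raise ValueError(
                f"embedding dim {X.shape[1]} does not match model dim {self.dim}"
            )
        hidden = np.maximum(0.0, X @ self.W1 + self.b1)
        logits = hidden @ self.W2 + self.b2
        # stable softmax: invariant to adding a constant to both logits
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)


def predict_proba(model: MLPModel, embeddings: np.ndarray) -> np.ndarray:
    """Positive-class probability per sentence embedding, in [0, 1]."""
    return model.forward(embeddings)[:, 1]


@dataclass
class SentenceDataset:
    """Class-balanced train/test partitions of embedded sentences for one
    category; ``provenance`` rows are (patient_id, doc_id, sent_index)."""

    category: int
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    provenance_train: list
    provenance_test: list


class InsufficientSentencesError(ValueError):
    pass


def build_sentence_dataset(
    tagged: dict[str, list[TaggedSentence]],
    category: int,
    embeddings_of,
    test_fraction: float = 0.2,
    seed: int = 0,
    include_unmatched: bool = False,
    group_by_patient: bool = False,
) -> SentenceDataset:
    """Build the balanced sentence dataset for one category.

    Positives are sentences with an affirmed match in *category*; negatives
    are drawn uniformly from sentences matched in other categories (and,
    when ``include_unmatched`` is set, keyword-free sentences too).  Both
    partitions are balanced by subsampling negatives to the positive count.
    ``embeddings_of`` maps a list of texts to an (n, dim) matrix.

    ``group_by_patient`` makes the train/test split patient-disjoint instead
    of row-random (guards against leakage at the cost of exact partition
    arithmetic).
    """
    rng = np.random.default_rng(seed)
    pos, neg = [], []
    for pid, sents in tagged.items():
        for ts in sents:
            cats_affirmed = ts.categories(AFFIRMED)
            prov = (ts.patient_id, ts.doc_id, ts.sentence.sent_index)
            if category in cats_affirmed:
                pos.append((ts.text, prov))
            elif ts.matches or include_unmatched:
                if category not in ts.categories():
                    neg.append((ts.text, prov))
    if len(pos) < 2:
        raise InsufficientSentencesError(
            f"category {category}: need >=2 affirmed sentences, found {len(pos)}"
        )
    if len(neg) < len(pos):
        raise InsufficientSentencesError(
            f"category {category}: need >= {len(pos)} out-of-category "
            f"sentences, found {len(neg)}"
        )
    neg_idx = rng.choice(len(neg), size=len(pos), replace=False)
    neg = [neg[i] for i in neg_idx]

    def _split(items):
        if group_by_patient:
            pids = sorted({p[1][0] for p in items})
            pids = [pids[i] for i in rng.permutation(len(pids))]
            n_test_p = max(1, round(test_fraction * len(pids)))
            test_pids = set(pids[:n_test_p])
            test = [it for it in items if it[1][0] in test_pids]
            train = [it for it in items if it[1][0] not in test_pids]
        else:
            order = rng.permutation(len(items))
            n_test = int(np.floor(test_fraction * len(items)))
            test = [items[i] for i in order[:n_test]]
            train = [items[i] for i in order[n_test:]]
        return train, test

    pos_train, pos_test = _split(pos)
    neg_train, neg_test = _split(neg)
    # keep partitions balanced (|pos - neg| <= 1) even under grouped splits
    for a, b in ((pos_train, neg_train), (pos_test, neg_test)):
        while len(a) > len(b) + 1:
            a.pop()
        while len(b) > len(a) + 1:
            b.pop()

    def _pack(pos_part, neg_part):
        texts = [t for t, _ in pos_part] + [t for t, _ in neg_part]
        y = np.array([1] * len(pos_part) + [0] * len(neg_part))
        prov = [p for _, p in pos_part] + [p for _, p in neg_part]
        X = embeddings_of(texts) if texts else np.empty((0, 0))
        return X, y, prov

    X_train, y_train, prov_train = _pack(pos_train, neg_train)
    X_test, y_test, prov_test = _pack(pos_test, neg_test)
    return SentenceDataset(category, X_train, y_train, X_test, y_test,
                           prov_train, prov_test)


def train_mlp(
    X: np.ndarray, y: np.ndarray, config: TrainConfig = TrainConfig()
) -> MLPModel:
    """Train the two-layer perceptron with momentum SGD on cross-entropy.

    Seeded He-uniform initialization; one pass per epoch over seeded
    shuffled mini-batches; per-epoch mean training loss is recorded on the
    returned model.  Aborts on non-finite loss.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n, dim = X.shape
    rng = np.random.default_rng(config.seed)

    def he_uniform(fan_in, shape):
        limit = np.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=shape)

    W1 = he_uniform(dim, (dim, config.hidden))
    b1 = np.zeros(config.hidden)
    W2 = he_uniform(config.hidden, (config.hidden, 2))
    b2 = np.zeros(2)
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)

    lr, mom = config.learning_rate, config.momentum
    onehot = np.eye(2)[y]
    history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, tb = X[idx], onehot[idx]
            z1 = xb @ W1 + b1
            h = np.maximum(0.0, z1)
            logits = h @ W2 + b2
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            probs = e / e.sum(axis=1, keepdims=True)
            loss = -np.mean(np.sum(tb * np.log(probs + 1e-12), axis=1))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}: {loss}"
                )
            losses.append(loss)

            dlogits = (probs - tb) / len(idx)
            dW2 = h.T @ dlogits
            db2 = dlogits.sum(axis=0)
            dh = dlogits @ W2.T
            dz1 = dh * (z1 > 0)
            dW1 = xb.T @ dz1
            db1 = dz1.sum(axis=0)

            vW2 = mom * vW2 - lr * dW2
            vb2 = mom * vb2 - lr * db2
            vW1 = mom * vW1 - lr * dW1
            vb1 = mom * vb1 - lr * db1
            W2 += vW2
            b2 += vb2
            W1 += vW1
            b1 += vb1
        history.append(float(np.mean(losses)))

    return MLPModel(W1=W1, b1=b1, W2=W2, b2=b2, train_config=config,
                    loss_history=history)


def evaluate_sentence_classifier(model: MLPModel, X_test, y_test) -> float:
    """Held-out accuracy at the 0.5 probability threshold."""
    if len(y_test) == 0:
        raise ValueError("empty test partition")
    pred = (predict_proba(model, X_test) >= 0.5).astype(int)
    return float(np.mean(pred == np.asarray(y_test)))


def save_model(model: MLPModel, path: str | Path) -> Path:
    """Persist weights (.npz) plus a JSON sidecar of the training config."""
    path = Path(path)
    np.savez(path, W1=model.W1, b1=model.b1, W2=model.W2, b2=model.b2)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "train_config": asdict(model.train_config),
        "loss_history": model.loss_history,
    }))
    return path


def load_model(path: str | Path) -> MLPModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    sidecar = path.with_suffix(".json")
    cfg, hist = TrainConfig(), []
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        cfg = TrainConfig(**meta["train_config"])
        hist = meta["loss_history"]
    return MLPModel(W1=data["W1"], b1=data["b1"], W2=data["W2"],
                    b2=data["b2"], train_config=cfg, loss_history=hist)
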