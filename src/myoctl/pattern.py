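"""Pattern-recognition control: training store, 16-32-8 ANN, recognizer, PCA.

The assistant watches a live band-power heat map and labels blocks of 20
consecutive 16-dimensional feature vectors with a hand motion; each block
becomes training data.  A three-layer perceptron (16 inputs, 32 hidden, 8
output neurons, sigmoid throughout) is trained by online error
backpropagation on squared error: the neuron assigned to a vector's label
has target 0.95, every other neuron 0.05.  Each time a block is added the
network continues training from its current weights for 200 passes over all
stored vectors at learning rate 0.1.  At run time a motion is recognized
when its output neuron fires at 0.65 or above; if no registered neuron
fires, the previously identified motion is held.

A PCA diagnostic on the stored training vectors (contribution ratios and a
PC1/PC2 projection) shows whether the assistant's selections are actually
separable by motion — mixed-up training data is the main failure mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .simulate import MotionLabel

__all__ = [
    "TrainingBlock",
    "TrainingStore",
    "AnnConfig",
    "AnnModel",
    "RecognizerState",
    "init_ann",
    "forward",
    "backprop_gradients",
    "train_epochs",
    "add_block_and_train",
    "recognize",
    "recognize_series",
    "pca_contribution",
    "save_model",
    "load_model",
]

BLOCK_SIZE = 20  # feature vectors per assistant-labeled training block


@dataclass(frozen=True)
class TrainingBlock:
    """20 consecutive feature vectors sharing one assistant-assigned label."""

    vectors: np.ndarray  # (20, 16)
    label: MotionLabel
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", v)
        if v.ndim != 2 or v.shape[0] != BLOCK_SIZE:
            raise ValueError(f"a training block holds exactly {BLOCK_SIZE} vectors")


@dataclass
class TrainingStore:
    """Ordered labeled blocks plus the label→output-neuron assignment.

    Labels are mapped to output neurons in first-seen order; at most 8
    distinct labels (one per output neuron) can be registered.
    """

    blocks: list[TrainingBlock] = field(default_factory=list)
    neuron_of: dict[MotionLabel, int] = field(default_factory=dict)

    def add(self, block: TrainingBlock) -> None:
        if block.label not in self.neuron_of:
            if len(self.neuron_of) >= 8:
                raise ValueError("at most 8 distinct motion labels can be registered")
            self.neuron_of[block.label] = len(self.neuron_of)
        self.blocks.append(block)

    def all_vectors(self) -> np.ndarray:
        return np.concatenate([b.vectors for b in self.blocks], axis=0)

    def all_targets(self, config: "AnnConfig") -> np.ndarray:
        """Per-vector target rows: hot at the label's neuron, cold elsewhere."""
        n_out = config.layers[-1]
        rows = []
        for b in self.blocks:
            t = np.full(n_out, config.target_cold)
            t[self.neuron_of[b.label]] = config.target_hot
            rows.append(np.tile(t, (len(b.vectors), 1)))
        return np.concatenate(rows, axis=0)

    def label_of_neuron(self) -> dict[int, MotionLabel]:
        return {n: lab for lab, n in self.neuron_of.items()}

    def to_json(self, path: str) -> None:
        payload = {
            "neuron_of": {int(lab): n for lab, n in self.neuron_of.items()},
            "blocks": [
                {
                    "label": int(b.label),
                    "timestamp": b.timestamp,
                    "vectors": b.vectors.tolist(),
                }
                for b in self.blocks
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "TrainingStore":
        with open(path) as fh:
            payload = json.load(fh)
        store = cls()
        store.neuron_of = {
            MotionLabel(int(k)): v for k, v in payload["neuron_of"].items()
        }
        store.blocks = [
            TrainingBlock(
                vectors=np.array(b["vectors"]),
                label=MotionLabel(b["label"]),
                timestamp=b.get("timestamp", 0.0),
            )
            for b in payload["blocks"]
        ]
        return store


@dataclass(frozen=True)
class AnnConfig:
    """Hyperparameters of the motion-recognition network."""

    layers: tuple[int, int, int] = (16, 32, 8)
    learning_rate: float = 0.1
    epochs: int = 200
    target_hot: float = 0.95
    target_cold: float = 0.05
    recognition_threshold: float = 0.65
    init_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layers) != 3 or any(n < 1 for n in self.layers):
            raise ValueError("layers must be three positive sizes")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if not (self.target_cold < self.recognition_threshold < self.target_hot):
            raise ValueError("need target_cold < recognition_threshold < target_hot")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class AnnModel:
    """Three-layer sigmoid perceptron: weights, biases and config."""

    w1: np.ndarray  # (hidden, in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (out, hidden)
    b2: np.ndarray  # (out,)
    config: AnnConfig

    def __post_init__(self) -> None:
        n_in, n_hid, n_out = self.config.layers
        if self.w1.shape != (n_hid, n_in) or self.w2.shape != (n_out, n_hid):
            raise ValueError("weight shapes do not match configured layer sizes")
        if self.b1.shape != (n_hid,) or self.b2.shape != (n_out,):
            raise ValueError("bias shapes do not match configured layer sizes")


def init_ann(config: AnnConfig = AnnConfig()) -> AnnModel:
    """Reproducible weight initialization, uniform on [−0.5, 0.5]."""
    n_in, n_hid, n_out = config.layers
    rng = np.random.default_rng(config.init_seed)
    return AnnModel(
        w1=rng.uniform(-0.5, 0.5, (n_hid, n_in)),
        b1=rng.uniform(-0.5, 0.5, n_hid),
        w2=rng.uniform(-0.5, 0.5, (n_out, n_hid)),
        b2=rng.uniform(-0.5, 0.5, n_out),
        config=config,
    )


def forward(model: AnnModel, x) -> np.ndarray:
    """Output activations ``sigmoid(W2 sigmoid(W1 x + b1) + b2)``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.config.layers[0],):
        raise ValueError(f"input must have {model.config.layers[0]} entries")
    h = _sigmoid(model.w1 @ x + model.b1)
    return _sigmoid(model.w2 @ h + model.b2)


def backprop_gradients(model: AnnModel, x, target):
    """Analytic gradients of ``E = 0.5 * sum((o - t)^2)`` for one vector."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(target, dtype=float)
    h = _sigmoid(model.w1 @ x + model.b1)
    o = _sigmoid(model.w2 @ h + model.b2)
    d2 = (o - t) * o * (1.0 - o)
    d1 = (model.w2.T @ d2) * h * (1.0 - h)
    return np.outer(d1, x), d1, np.outer(d2, h), d2


def train_epochs(model: AnnModel, vectors: np.ndarray, targets: np.ndarray, epochs: int | None = None) -> AnnModel:
    """Online (per-vector) gradient descent in stored order, in place.

    No shuffling, momentum or early stopping — updates are applied vector by
    vector for ``epochs`` passes, which keeps retraining fully deterministic.
    """
    if epochs is None:
        epochs = model.config.epochs
    lr = model.config.learning_rate
    for _ in range(epochs):
        for x, t in zip(vectors, targets):
            gw1, gb1, gw2, gb2 = backprop_gradients(model, x, t)
            model.w1 -= lr * gw1
            model.b1 -= lr * gb1
            model.w2 -= lr * gw2
            model.b2 -= lr * gb2
    return model


def add_block_and_train(model: AnnModel, store: TrainingStore, block: TrainingBlock) -> tuple[AnnModel, float]:
    """Register a new labeled block and retrain on the whole store.

    Training continues from the model's current weights for the configured
    number of passes over all stored vectors.  Returns the model and its
    training-set recognition accuracy (fraction of stored vectors whose
    firing neuron matches their label; held decisions count as misses).
    """
    store.add(block)
    vectors = store.all_vectors()
    targets = store.all_targets(model.config)
    train_epochs(model, vectors, targets)
    labels = np.concatenate([[int(b.label)] * len(b.vectors) for b in store.blocks])
    correct = 0
    for x, lab in zip(vectors, labels):
        out = forward(model, x)
        decided = _decide(out, store, model.config.recognition_threshold)
        if decided is not None and int(decided) == lab:
            correct += 1
    return model, correct / len(labels)


def _decide(outputs: np.ndarray, store: TrainingStore, threshold: float) -> MotionLabel | None:
    """Firing registered neuron with the largest output, or None.

    Only neurons with a registered label compete, so the recognizer can
    never emit an unregistered motion; exact ties go to the lowest index.
    """
    if not store.neuron_of:
        return None
    neurons = sorted(store.neuron_of.values())
    vals = outputs[neurons]
    best = neurons[int(np.argmax(vals))]
    if outputs[best] >= threshold:
        return store.label_of_neuron()[best]
    return None


@dataclass
class RecognizerState:
    """Hold-previous memory of the recognizer."""

    previous_label: MotionLabel = MotionLabel.REST


def recognize(model: AnnModel, x, store: TrainingStore, state: RecognizerState) -> MotionLabel:
    """Identify the motion for one feature vector (mutates ``state``).

    If the best registered output neuron reaches the recognition threshold
    its motion is identified and remembered; otherwise the motion identified
    previously is re-issued.
    """
    out = forward(model, x)
    decided = _decide(out, store, model.config.recognition_threshold)
    if decided is not None:
        state.previous_label = decided
    return state.previous_label


def recognize_series(model: AnnModel, features: np.ndarray, store: TrainingStore) -> np.ndarray:
    """Recognizer decisions over a feature series (initial hold = rest)."""
    state = RecognizerState()
    return np.array(
        [int(recognize(model, x, store, state)) for x in features], dtype=np.int8
    )


def pca_contribution(store: TrainingStore):
    """PCA separability diagnostic on all stored training vectors.

    Eigendecomposition of the covariance of the mean-centered (but not
    standardized) vectors.  Returns ``(ratios, scores, labels)``: per-component
    contribution ratios in descending order, the PC1/PC2 scores of every
    vector, and each vector's motion label.  The cumulative ratio through
    PC2, ``ratios[:2].sum()``, is the usual single-number summary.
    """
    if not store.blocks:
        raise ValueError("training store is empty")
    x = store.all_vectors()
    if x.shape[0] < 2:
        raise ValueError("need at least 2 vectors for PCA")
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    total = evals.sum()
    if total <= 0:
        raise ValueError("degenerate (constant) training data")
    ratios = evals / total
    scores = centered @ evecs[:, order[:2]] if cov.shape[0] >= 2 else centered @ evecs[:, order[:1]]
    labels = np.concatenate([[int(b.label)] * len(b.vectors) for b in store.blocks])
    return ratios, scores, labels


def save_model(model: AnnModel, store: TrainingStore, path: str) -> None:
    """Self-describing JSON snapshot of config, label map and weights."""
    payload = {
        "config": {
            "layers": list(model.config.layers),
            "learning_rate": model.config.learning_rate,
            "epochs": model.config.epochs,
            "target_hot": model.config.target_hot,
            "target_cold": model.config.target_cold,
            "recognition_threshold": model.config.recognition_threshold,
            "init_seed": model.config.init_seed,
        },
        "neuron_of": {int(lab): n for lab, n in store.neuron_of.items()},
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> tuple[AnnModel, TrainingStore]:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    config = AnnConfig(
        layers=tuple(cfg["layers"]),
        learning_rate=cfg["learning_rate"],
        epochs=cfg["epochs"],
        target_hot=cfg["target_hot"],
        target_cold=cfg["target_cold"],
        recognition_threshold=cfg["recognition_threshold"],
        init_seed=cfg["init_seed"],
    )
    model = AnnModel(
        w1=np.array(payload["w1"]),
        b1=np.array(payload["b1"]),
        w2=np.array(payload["w2"]),
        b2=np.array(payload["b2"]),
        config=config,
    )
    store = TrainingStore()
    store.neuron_of = {MotionLabel(int(k)): v for k, v in payload["neuron_of"].items()}
    return model, store
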