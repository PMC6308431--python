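"""Feedforward ANN training and three-network ensemble grading.

Grades follow the IETS quality codes restricted to viable embryos:
1 = excellent/good, 2 = fair, 3 = poor.  A network is described by a
9-gene architecture chromosome (hidden sizes, per-layer transfer
functions, output transfer function, training function, number of hidden
layers) so that the genetic search can evolve it.  Networks are trained
by full-batch backpropagation on one-hot cross-entropy with early
stopping on the validation split; the canonical data split is 70%
train / 15% validation / 15% test, stratified by grade.

The forward/backward passes are implemented directly in numpy because
the architecture space (per-layer transfer functions, Rprop-style
training) has to match the chromosome encoding exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

GRADE_LABELS = {1: "excellent_good", 2: "fair", 3: "poor"}
N_CLASSES = 3

TRANSFER_FUNCTIONS = ("logistic_sigmoid", "tanh_sigmoid", "linear")
TRAIN_FUNCTIONS = ("gradient_descent", "gradient_descent_momentum", "rprop")
MAX_NEURONS = 64

DEFAULT_MAX_EPOCHS = 200
DEFAULT_PATIENCE = 25


class StratificationError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


class EnsembleSizeError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class Architecture:
    """The 9-gene chromosome describing one candidate network.

    Genes past ``n_hidden_layers`` are carried in the genome but inert,
    so crossover/mutation can still act on them.
    """

    n_hidden1: int = 16
    n_hidden2: int = 8
    n_hidden3: int = 4
    tf_hidden1: str = "tanh_sigmoid"
    tf_hidden2: str = "tanh_sigmoid"
    tf_hidden3: str = "tanh_sigmoid"
    tf_output: str = "logistic_sigmoid"
    train_fn: str = "rprop"
    n_hidden_layers: int = 1

    def __post_init__(self) -> None:
        for n in (self.n_hidden1, self.n_hidden2, self.n_hidden3):
            if not 1 <= n <= MAX_NEURONS:
                raise ValueError(f"hidden size {n} outside [1, {MAX_NEURONS}]")
        for tf in (self.tf_hidden1, self.tf_hidden2, self.tf_hidden3, self.tf_output):
            if tf not in TRANSFER_FUNCTIONS:
                raise ValueError(f"unknown transfer function {tf!r}")
        if self.train_fn not in TRAIN_FUNCTIONS:
            raise ValueError(f"unknown training function {self.train_fn!r}")
        if self.n_hidden_layers not in (1, 2, 3):
            raise ValueError("n_hidden_layers must be 1, 2 or 3")

    @property
    def genes(self) -> tuple:
        return (self.n_hidden1, self.n_hidden2, self.n_hidden3,
                self.tf_hidden1, self.tf_hidden2, self.tf_hidden3,
                self.tf_output, self.train_fn, self.n_hidden_layers)

    @classmethod
    def from_genes(cls, genes: Sequence) -> "Architecture":
        return cls(*genes)

    def active_layers(self) -> list[tuple[int, str]]:
        sizes = (self.n_hidden1, self.n_hidden2, self.n_hidden3)
        tfs = (self.tf_hidden1, self.tf_hidden2, self.tf_hidden3)
        return [(sizes[k], tfs[k]) for k in range(self.n_hidden_layers)]


def _activate(z: np.ndarray, tf: str) -> np.ndarray:
    if tf == "logistic_sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    if tf == "tanh_sigmoid":
        return np.tanh(z)
    return z


def _activate_deriv(a: np.ndarray, tf: str) -> np.ndarray:
    # derivatives expressed through the activation value a = f(z)
    if tf == "logistic_sigmoid":
        return a * (1.0 - a)
    if tf == "tanh_sigmoid":
        return 1.0 - a ** 2
    return np.ones_like(a)


def _softmax(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedANN:
    architecture: Architecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_schema: tuple[str, ...]
    norm_mean: np.ndarray
    norm_std: np.ndarray
    class_labels: dict[int, str] = field(default_factory=lambda: dict(GRADE_LABELS))
    training_log: list[dict] = field(default_factory=list)
    rng_seed: int = 0

    # -- forward pass ---------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        a = x
        layers = self.architecture.active_layers() + [(N_CLASSES, self.architecture.tf_output)]
        for (w, b, (_, tf)) in zip(self.weights, self.biases, layers):
            a = _activate(a @ w + b, tf)
        return a

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Normalized class scores (sum to 1) for reporting."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        xn = (x - self.norm_mean) / self.norm_std
        return _softmax(self._forward(xn))

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "architecture": asdict(self.architecture),
            "input_schema": list(self.input_schema),
            "class_labels": {str(k): v for k, v in self.class_labels.items()},
            "norm_mean": self.norm_mean.tolist(),
            "norm_std": self.norm_std.tolist(),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedANN":
        d = json.loads(Path(path).read_text())
        return cls(
            architecture=Architecture(**d["architecture"]),
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            input_schema=tuple(d["input_schema"]),
            norm_mean=np.asarray(d["norm_mean"]),
            norm_std=np.asarray(d["norm_std"]),
            class_labels={int(k): v for k, v in d["class_labels"].items()},
            rng_seed=d.get("rng_seed", 0),
        )


@dataclass
class GradePrediction:
    per_ann: tuple[int, int, int]
    per_ann_scores: np.ndarray
    mode_grade: Optional[int]
    final_grade: int


def split_dataset(features: np.ndarray, labels: np.ndarray, seed: int,
                  fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)):
    """Stratified 70/15/15 split, deterministic per seed.

    Returns ((x_tr, y_tr), (x_va, y_va), (x_te, y_te)).  Every class must
    be present; each class contributes at least one sample to each split.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < N_CLASSES:
        raise StratificationError(
            f"all {N_CLASSES} grade classes must be present, found {list(classes)}")
    rng = np.random.default_rng(seed)
    idx_parts: list[list[int]] = [[], [], []]
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        n_tr = min(n_tr, n - 2)
        n_va = max(1, min(n_va, n - n_tr - 1))
        idx_parts[0].extend(idx[:n_tr])
        idx_parts[1].extend(idx[n_tr:n_tr + n_va])
        idx_parts[2].extend(idx[n_tr + n_va:])
    out = []
    for part in idx_parts:
        part = np.sort(np.asarray(part))
        out.append((features[part], labels[part]))
    return tuple(out)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    y = np.zeros((len(labels), N_CLASSES))
    y[np.arange(len(labels)), np.asarray(labels, dtype=int) - 1] = 1.0
    return y


def _init_params(arch: Architecture, n_inputs: int, rng: np.random.Generator):
    sizes = [n_inputs] + [s for s, _ in arch.active_layers()] + [N_CLASSES]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (a + b))
        weights.append(rng.uniform(-limit, limit, size=(a, b)))
        biases.append(np.zeros(b))
    return weights, biases


def _loss_and_grads(weights, biases, arch: Architecture, x, y):
    tfs = [tf for _, tf in arch.active_layers()] + [arch.tf_output]
    acts = [x]
    a = x
    for w, b, tf in zip(weights, biases, tfs):
        a = _activate(a @ w + b, tf)
        acts.append(a)
    scores = _softmax(acts[-1])
    n = x.shape[0]
    loss = float(-(y * np.log(np.clip(scores, 1e-300, None))).sum() / n)
    delta = (scores - y) / n  # dL/d(output activation) via softmax CE
    gw, gb = [None] * len(weights), [None] * len(biases)
    for layer in range(len(weights) - 1, -1, -1):
        delta = delta * _activate_deriv(acts[layer + 1], tfs[layer])
        gw[layer] = acts[layer].T @ delta
        gb[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ weights[layer].T
    return loss, scores, gw, gb


def _misclassification(scores: np.ndarray, labels: np.ndarray) -> float:
    pred = np.argmax(scores, axis=1) + 1
    return float((pred != np.asarray(labels)).mean())


def train_ann(train: tuple[np.ndarray, np.ndarray],
              validation: tuple[np.ndarray, np.ndarray],
              arch: Architecture,
              seed: int = 0,
              max_epochs: int = DEFAULT_MAX_EPOCHS,
              patience: int = DEFAULT_PATIENCE,
              learning_rate: float = 0.05,
              input_schema: Optional[Sequence[str]] = None) -> TrainedANN:
    """Full-batch backpropagation with validation early stopping.

    ``arch.train_fn`` selects the update rule: plain gradient descent,
    gradient descent with momentum 0.9, or Rprop (sign-based step-size
    adaptation, eta+ = 1.2, eta- = 0.5).  The best-validation weights are
    restored at the end.  Fully deterministic for fixed inputs and seed.
    """
    x_tr, y_lab = np.asarray(train[0], dtype=np.float64), np.asarray(train[1])
    x_va, yv_lab = np.asarray(validation[0], dtype=np.float64), np.asarray(validation[1])
    mean = x_tr.mean(axis=0)
    std = x_tr.std(axis=0)
    std[std < 1e-12] = 1.0
    xn_tr = (x_tr - mean) / std
    xn_va = (x_va - mean) / std
    y_tr = _one_hot(y_lab)

    rng = np.random.default_rng(seed)
    weights, biases = _init_params(arch, x_tr.shape[1], rng)

    if input_schema is None:
        input_schema = tuple(f"x{k}" for k in range(x_tr.shape[1]))

    ann = TrainedANN(architecture=arch, weights=weights, biases=biases,
                     input_schema=tuple(input_schema), norm_mean=mean,
                     norm_std=std, rng_seed=seed)
    if max_epochs <= 0:
        return ann

    # per-parameter state for momentum / rprop
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    step_w = [np.full_like(w, 0.01) for w in weights]
    step_b = [np.full_like(b, 0.01) for b in biases]
    prev_gw = [np.zeros_like(w) for w in weights]
    prev_gb = [np.zeros_like(b) for b in biases]

    best_val = np.inf
    best_params = ([w.copy() for w in weights], [b.copy() for b in biases])
    stale = 0
    log: list[dict] = []

    for epoch in range(max_epochs):
        loss, _, gw, gb = _loss_and_grads(weights, biases, arch, xn_tr, y_tr)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")
        if arch.train_fn == "gradient_descent":
            for k in range(len(weights)):
                weights[k] -= learning_rate * gw[k]
                biases[k] -= learning_rate * gb[k]
        elif arch.train_fn == "gradient_descent_momentum":
            for k in range(len(weights)):
                vel_w[k] = 0.9 * vel_w[k] - learning_rate * gw[k]
                vel_b[k] = 0.9 * vel_b[k] - learning_rate * gb[k]
                weights[k] += vel_w[k]
                biases[k] += vel_b[k]
        else:  # iRprop- : sign-based step adaptation, no step on sign flip
            for k in range(len(weights)):
                for which, (g, pg, st, p) in enumerate(
                        ((gw[k], prev_gw[k], step_w[k], weights[k]),
                         (gb[k], prev_gb[k], step_b[k], biases[k]))):
                    sign = np.sign(g)
                    agree = sign * np.sign(pg)
                    st *= np.where(agree > 0, 1.2, np.where(agree < 0, 0.5, 1.0))
                    np.clip(st, 1e-8, 1.0, out=st)
                    p -= np.where(agree < 0, 0.0, sign * st)
                    stored = np.where(agree < 0, 0.0, g)
                    if which == 0:
                        prev_gw[k] = stored
                    else:
                        prev_gb[k] = stored

        _, val_scores, _, _ = _loss_and_grads(weights, biases, arch, xn_va, _one_hot(yv_lab))
        val_err = _misclassification(val_scores, yv_lab)
        log.append({"epoch": epoch, "train_loss": loss, "val_error": val_err})
        if val_err < best_val - 1e-12:
            best_val = val_err
            best_params = ([w.copy() for w in weights], [b.copy() for b in biases])
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break

    ann.weights, ann.biases = best_params
    ann.training_log = log
    return ann


def predict(ann: TrainedANN, x: np.ndarray) -> tuple[int, np.ndarray]:
    """Grade one feature vector; ties go to the worse (higher) grade."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape[0] != len(ann.input_schema):
        raise SchemaError(
            f"expected {len(ann.input_schema)} features, got {x.shape[0]}")
    s = ann.scores(x)[0]
    best = s.max()
    grade = int(np.max(np.flatnonzero(s >= best - 1e-12))) + 1
    return grade, s


def accuracy(ann: TrainedANN, x: np.ndarray, labels: np.ndarray) -> float:
    s = ann.scores(np.asarray(x))
    pred = np.argmax(s, axis=1) + 1
    return float((pred == np.asarray(labels)).mean())


def ensemble_predict(anns: Sequence[TrainedANN], x: np.ndarray) -> GradePrediction:
    """Mode vote of exactly three networks.

    If at least two networks agree, their grade is the mode; with a
    three-way disagreement the mode is undefined and the median ordinal
    grade (always 2 in that case) is the fallback final grade.
    """
    if len(anns) != 3:
        raise EnsembleSizeError(f"ensemble needs exactly 3 networks, got {len(anns)}")
    schemas = {a.input_schema for a in anns}
    if len(schemas) != 1:
        raise SchemaError("ensemble networks must share the same input schema")
    grades, scores = [], []
    for ann in anns:
        g, s = predict(ann, x)
        grades.append(g)
        scores.append(s)
    counts = {g: grades.count(g) for g in set(grades)}
    top = max(counts.values())
    if top >= 2:
        mode = min(g for g, c in counts.items() if c == top)
        final = mode
    else:
        mode = None
        final = int(np.median(grades))
    return GradePrediction(per_ann=tuple(grades), per_ann_scores=np.vstack(scores),
                           mode_grade=mode, final_grade=final)


def ensemble_accuracy(anns: Sequence[TrainedANN], x: np.ndarray,
                      labels: np.ndarray) -> float:
    preds = [ensemble_predict(anns, row).final_grade for row in np.asarray(x)]
    return float((np.asarray(preds) == np.asarray(labels)).mean())
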