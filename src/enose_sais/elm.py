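"""Multi-class Extreme Learning Machine (ELM).

A single-hidden-layer network whose hidden weights are random and fixed:
H = sigmoid(X W^T + b) with W ~ U(-1, 1), b ~ U(0, 1) from a seeded
generator, and the output weights are the least-squares solution
beta = pinv(H) @ one_hot(labels).  Prediction is the argmax of H beta over
classes.  Fast, deterministic given the seed, and the standard discriminator
for e-nose feature vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import InvalidParameterError, ShapeMismatchError


@dataclass
class ELMModel:
    input_weights: np.ndarray          # (L, D)
    biases: np.ndarray                 # (L,)
    output_weights: np.ndarray         # (L, C)
    class_ids: np.ndarray              # (C,) sorted ascending
    activation: str = "sigmoid"
    seed: int = 0

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]

    def save(self, path) -> None:
        """Single-file JSON dump (header + matrices)."""
        payload = {
            "L": self.n_hidden,
            "D": self.n_features,
            "C": len(self.class_ids),
            "seed": self.seed,
            "activation": self.activation,
            "class_ids": np.asarray(self.class_ids).tolist(),
            "input_weights": self.input_weights.tolist(),
            "biases": self.biases.tolist(),
            "output_weights": self.output_weights.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ELMModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            input_weights=np.array(payload["input_weights"], dtype=float),
            biases=np.array(payload["biases"], dtype=float),
            output_weights=np.array(payload["output_weights"], dtype=float),
            class_ids=np.array(payload["class_ids"], dtype=int),
            activation=payload["activation"],
            seed=int(payload["seed"]),
        )


def _hidden(model_or_w, biases, X):
    return expit(X @ model_or_w.T + biases)


def elm_train(features: np.ndarray, labels: np.ndarray, L: int = 200, seed: int = 0) -> ELMModel:
    """Fit an ELM on labeled feature vectors.

    Hidden-layer weights/biases come from ``np.random.default_rng(seed)`` so
    (seed, L, D) fully determines the model; output weights are the
    Moore–Penrose least-squares fit to one-hot targets.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ShapeMismatchError("features must be (N, D) with one label per row")
    if L < 1:
        raise InvalidParameterError("need at least one hidden node")
    class_ids = np.unique(y)
    if class_ids.size < 2:
        raise InvalidParameterError("training requires at least two classes")
    if X.shape[0] < class_ids.size:
        raise InvalidParameterError("need at least as many samples as classes")

    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L, X.shape[1]))
    b = rng.uniform(0.0, 1.0, size=L)
    H = _hidden(W, b, X)
    T = (y[:, None] == class_ids[None, :]).astype(float)
    beta = np.linalg.pinv(H) @ T
    return ELMModel(
        input_weights=W,
        biases=b,
        output_weights=beta,
        class_ids=class_ids.astype(int),
        seed=seed,
    )


def elm_predict(model: ELMModel, features: np.ndarray) -> np.ndarray:
    """Predicted class ids (argmax of class scores; ties → lowest class id)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ShapeMismatchError(
            f"features must be (M, {model.n_features}); got {X.shape}"
        )
    scores = elm_scores(model, X)
    return model.class_ids[np.argmax(scores, axis=1)]


def elm_scores(model: ELMModel, features: np.ndarray) -> np.ndarray:
    """Raw per-class scores H·beta (one row per sample)."""
    H = _hidden(model.input_weights, model.biases, np.asarray(features, dtype=float))
    return H @ model.output_weights
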