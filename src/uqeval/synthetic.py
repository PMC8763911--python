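"""Synthetic binary tasks with known Bayes error, and a small dropout
network to act as the probabilistic classifier under study.

The generator draws the two classes from isotropic Gaussians a distance
``mean_separation`` apart (spread ``sigma`` within class).  For equal
priors the optimal decision rule is the midpoint hyperplane and its error
rate has the closed form ``Phi(-separation / (2 sigma))`` — an analytic
anchor that lets every downstream uncertainty metric be checked against a
task whose ground-truth difficulty is known exactly.  The defaults
emulate an imperfect medical-image classifier: a task with roughly 16%
irreducible error, where mistakes cluster near the class boundary and
should therefore attract high predictive entropy.

The fixture classifier is a compact fully connected network (ReLU hidden
layers, softmax head, inverted dropout, Adam on cross-entropy) written
directly on numpy so dropout stays active at inference, which is what the
MC-dropout posterior requires.  During training dropout masks are drawn
per sample and per step; during a stochastic forward pass one mask per
hidden layer is drawn for the whole batch, i.e. one sampled weight
configuration per pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._utils import as_generator
from .errors import ContractViolationError, UnsupportedTaskError, ValidationError

__all__ = [
    "SyntheticTaskSpec",
    "FixtureModelConfig",
    "DropoutMLP",
    "generate_dataset",
    "bayes_error",
    "train_fixture_classifier",
    "make_fixture_ensemble",
    "save_dataset",
    "load_dataset",
    "CXR_LIKE_PRIORS",
    "DEFAULT_ENSEMBLE_WIDTH_RANGES",
]

#: class-prior preset mirroring a 131 normal / 391 positive composition
CXR_LIKE_PRIORS = (0.25, 0.75)

#: per-layer (min, max) width ranges for random ensemble architectures,
#: desk-scale counterparts of (512,1024)/(128,512)/(8,128)
DEFAULT_ENSEMBLE_WIDTH_RANGES = ((16, 64), (8, 32), (4, 16))


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Generative parameters of a two-Gaussian classification task.

    Class 0 sits at -separation/2 and class 1 at +separation/2 along the
    first feature axis; all features have within-class standard deviation
    ``spread``.  ``mean_separation / (2 * spread)`` is the signal-to-noise
    ratio that fixes the Bayes error for equal priors.
    """

    n_samples: int = 2000
    n_features: int = 2
    class_priors: tuple[float, float] = (0.5, 0.5)
    mean_separation: float = 2.0
    spread: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        if self.spread <= 0:
            raise ValidationError("spread (sigma) must be > 0")
        if self.mean_separation < 0:
            raise ValidationError("mean_separation must be >= 0")
        p = np.asarray(self.class_priors, dtype=float)
        if p.shape != (2,) or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("class_priors must be two positive values summing to 1")

    def to_dict(self) -> dict:
        return {"n_samples": self.n_samples, "n_features": self.n_features,
                "class_priors": list(self.class_priors),
                "mean_separation": self.mean_separation,
                "spread": self.spread, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTaskSpec":
        d = dict(d)
        d["class_priors"] = tuple(d.get("class_priors", (0.5, 0.5)))
        return cls(**d)


def generate_dataset(spec: SyntheticTaskSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (features, labels) from the two-Gaussian task; deterministic
    under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n_samples) < spec.class_priors[1]).astype(int)
    X = spec.spread * rng.standard_normal((spec.n_samples, spec.n_features))
    X[:, 0] += np.where(y == 1, 0.5, -0.5) * spec.mean_separation
    return X, y


def bayes_error(spec: SyntheticTaskSpec) -> float:
    """Closed-form minimum error rate, Phi(-separation / (2 sigma)).

    Only defined here for the equal-prior isotropic case (the midpoint
    rule is then optimal); other prior configurations raise.
    """
    if abs(spec.class_priors[0] - spec.class_priors[1]) > 1e-9:
        raise UnsupportedTaskError(
            "closed-form Bayes error implemented for equal class priors only")
    return float(norm.cdf(-spec.mean_separation / (2.0 * spec.spread)))


def save_dataset(features: np.ndarray, labels: np.ndarray, path,
                 spec: SyntheticTaskSpec | None = None) -> Path:
    """Write a dataset as CSV (feature columns f0..fd-1 plus ``label``);
    if ``spec`` is given, a JSON sidecar ``<stem>.spec.json`` records it."""
    path = Path(path)
    d = features.shape[1]
    frame = pd.DataFrame(features, columns=[f"f{i}" for i in range(d)])
    frame["label"] = labels
    frame.to_csv(path, index=False)
    if spec is not None:
        path.with_suffix(".spec.json").write_text(json.dumps(spec.to_dict(), indent=2))
    return path


def load_dataset(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a dataset written by :func:`save_dataset`."""
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise ValidationError(f"{path}: no 'label' column")
    y = frame.pop("label").to_numpy(dtype=int)
    return frame.to_numpy(dtype=float), y


@dataclass(frozen=True)
class FixtureModelConfig:
    """Training configuration for the fixture network.

    ``hidden_layer_sizes`` entries are either fixed widths (ints) or
    (min, max) ranges from which a width is drawn — the latter is how
    ensemble members get distinct architectures.  Defaults: two hidden
    layers of 32/16 units, dropout 0.25 on the hidden (fully connected)
    layers, 200 epochs of Adam at learning rate 1e-3.
    """

    hidden_layer_sizes: tuple = (32, 16)
    dropout_rate: float = 0.25
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValidationError("learning_rate and batch_size must be positive")
        if len(self.hidden_layer_sizes) == 0:
            raise ValidationError("need at least one hidden layer")


def _resolve_architecture(sizes: Sequence, rng: np.random.Generator,
                          vary_depth: bool = False) -> tuple[int, ...]:
    """Materialise widths: ints pass through, (min, max) pairs are drawn.
    With ``vary_depth`` the number of layers is itself drawn between 2
    and min(3, available ranges)."""
    sizes = list(sizes)
    if vary_depth and len(sizes) >= 2:
        n_layers = int(rng.integers(2, min(3, len(sizes)) + 1))
        sizes = sizes[:n_layers]
    widths = []
    for s in sizes:
        if np.isscalar(s):
            widths.append(int(s))
        else:
            lo, hi = s
            widths.append(int(rng.integers(int(lo), int(hi) + 1)))
    if any(w < 1 for w in widths):
        raise ValidationError("hidden layer widths must be >= 1")
    return tuple(widths)


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DropoutMLP:
    """Fully connected softmax classifier with inverted dropout.

    Satisfies the stochastic-forward-pass contract used by the posterior
    module: ``predict_proba(X, stochastic=True, rng=...)`` draws one
    dropout mask per hidden layer (shared across the batch) and scales
    kept units by 1/(1-p); ``stochastic=False`` uses the deterministic
    weight-averaged network.
    """

    def __init__(self, n_features: int, hidden_layer_sizes: Sequence[int],
                 n_classes: int, dropout_rate: float, rng):
        rng = as_generator(rng)
        self.n_features = int(n_features)
        self.hidden_layer_sizes = tuple(int(s) for s in hidden_layer_sizes)
        self.n_classes = int(n_classes)
        self.dropout_rate = float(dropout_rate)
        sizes = [self.n_features, *self.hidden_layer_sizes, self.n_classes]
        # He-normal initialisation, zero biases
        self.weights = [rng.normal(0.0, np.sqrt(2.0 / fi), (fi, fo))
                        for fi, fo in zip(sizes[:-1], sizes[1:])]
        self.biases = [np.zeros(fo) for fo in sizes[1:]]
        self.meta: dict = {"hidden_layer_sizes": list(self.hidden_layer_sizes),
                           "dropout_rate": self.dropout_rate}

    @property
    def supports_stochastic(self) -> bool:
        return self.dropout_rate > 0.0

    # -- inference -----------------------------------------------------

    def _forward(self, X: np.ndarray, masks=None) -> np.ndarray:
        h = X
        for layer, (W, b) in enumerate(zip(self.weights[:-1], self.biases[:-1])):
            h = _relu(h @ W + b)
            if masks is not None:
                h = h * masks[layer]
        return _softmax(h @ self.weights[-1] + self.biases[-1])

    def _draw_unit_masks(self, rng: np.random.Generator) -> list[np.ndarray]:
        p = self.dropout_rate
        return [(rng.random(w) >= p) / (1.0 - p) for w in self.hidden_layer_sizes]

    def predict_proba(self, X, *, stochastic: bool = False, rng=None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features} features, got {X.shape[1]}")
        if not stochastic:
            return self._forward(X)
        if not self.supports_stochastic:
            raise ContractViolationError(
                "supports_stochastic is False (dropout_rate = 0); "
                "stochastic forward passes would all be identical")
        masks = self._draw_unit_masks(as_generator(rng))
        return self._forward(X, masks)

    # -- training ------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, *, epochs: int,
            learning_rate: float, batch_size: int, rng) -> "DropoutMLP":
        """Minimise softmax cross-entropy with Adam; dropout masks are
        per-sample during training."""
        rng = as_generator(rng)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = len(X)
        onehot = np.eye(self.n_classes)[y]
        p = self.dropout_rate
        b1, b2, eps = 0.9, 0.999, 1e-8
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        step = 0
        n_hidden = len(self.hidden_layer_sizes)
        for _ in range(epochs):
            perm = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = perm[start:start + batch_size]
                xb, yb = X[idx], onehot[idx]
                # forward, caching activations, pre-activations and masks
                acts, pres, masks = [xb], [], []
                h = xb
                for layer in range(n_hidden):
                    z = h @ self.weights[layer] + self.biases[layer]
                    h = _relu(z)
                    if p > 0:
                        mask = (rng.random(h.shape) >= p) / (1.0 - p)
                        h = h * mask
                    else:
                        mask = None
                    pres.append(z)
                    masks.append(mask)
                    acts.append(h)
                probs = _softmax(h @ self.weights[-1] + self.biases[-1])
                delta = (probs - yb) / len(xb)
                grads_w = [np.empty(0)] * len(self.weights)
                grads_b = [np.empty(0)] * len(self.biases)
                for layer in range(len(self.weights) - 1, -1, -1):
                    grads_w[layer] = acts[layer].T @ delta
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self.weights[layer].T
                        if masks[layer - 1] is not None:
                            delta = delta * masks[layer - 1]
                        delta = delta * (pres[layer - 1] > 0)
                step += 1
                c1, c2 = 1 - b1 ** step, 1 - b2 ** step
                for layer in range(len(self.weights)):
                    m_w[layer] = b1 * m_w[layer] + (1 - b1) * grads_w[layer]
                    v_w[layer] = b2 * v_w[layer] + (1 - b2) * grads_w[layer] ** 2
                    self.weights[layer] -= learning_rate * (m_w[layer] / c1) / (
                        np.sqrt(v_w[layer] / c2) + eps)
                    m_b[layer] = b1 * m_b[layer] + (1 - b1) * grads_b[layer]
                    v_b[layer] = b2 * v_b[layer] + (1 - b2) * grads_b[layer] ** 2
                    self.biases[layer] -= learning_rate * (m_b[layer] / c1) / (
                        np.sqrt(v_b[layer] / c2) + eps)
        return self

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "hidden_layer_sizes": list(self.hidden_layer_sizes),
            "n_classes": self.n_classes,
            "dropout_rate": self.dropout_rate,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DropoutMLP":
        model = cls(d["n_features"], d["hidden_layer_sizes"], d["n_classes"],
                    d["dropout_rate"], rng=0)
        model.weights = [np.asarray(w, dtype=float) for w in d["weights"]]
        model.biases = [np.asarray(b, dtype=float) for b in d["biases"]]
        model.meta = dict(d.get("meta", {}))
        return model

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def load(cls, path) -> "DropoutMLP":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def train_fixture_classifier(features: np.ndarray, labels: np.ndarray,
                             config: FixtureModelConfig = FixtureModelConfig(),
                             *, vary_depth: bool = False) -> DropoutMLP:
    """Train one dropout network on a 75/25 train/validation split.

    All randomness (architecture draw when ranges are configured,
    initialisation, split, shuffling, dropout masks) derives from named
    child streams of ``config.seed``, so a config+seed pair maps to one
    reproducible model.  Held-out accuracy on the 25% validation part is
    recorded in ``model.meta["val_accuracy"]``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("labels contain a single class; need >= 2")
    n_classes = int(classes.max()) + 1

    ss_arch, ss_init, ss_split, ss_train = np.random.SeedSequence(config.seed).spawn(4)
    widths = _resolve_architecture(config.hidden_layer_sizes,
                                   np.random.default_rng(ss_arch), vary_depth=vary_depth)
    model = DropoutMLP(features.shape[1], widths, n_classes,
                       config.dropout_rate, rng=np.random.default_rng(ss_init))

    n = len(features)
    perm = np.random.default_rng(ss_split).permutation(n)
    n_train = int(round(0.75 * n))
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    model.fit(features[train_idx], labels[train_idx], epochs=config.epochs,
              learning_rate=config.learning_rate, batch_size=config.batch_size,
              rng=np.random.default_rng(ss_train))

    if len(val_idx):
        val_pred = model.predict_proba(features[val_idx]).argmax(axis=1)
        model.meta["val_accuracy"] = float((val_pred == labels[val_idx]).mean())
    model.meta.update(seed=config.seed, epochs=config.epochs,
                      learning_rate=config.learning_rate)
    return model


def make_fixture_ensemble(features: np.ndarray, labels: np.ndarray,
                          base_config: FixtureModelConfig = FixtureModelConfig(),
                          n_members: int = 30, seed: int = 0) -> list[DropoutMLP]:
    """Train an ensemble whose members differ in architecture and
    initialisation.

    Each member's hidden depth is drawn between 2 and 3 and its widths
    from per-layer ranges (``DEFAULT_ENSEMBLE_WIDTH_RANGES`` unless
    ``base_config.hidden_layer_sizes`` already holds ranges); member i
    trains under child stream i of ``seed``.  Architectures are recorded
    in each member's ``meta``.
    """
    if n_members < 1:
        raise ValidationError("n_members must be >= 1")
    sizes = base_config.hidden_layer_sizes
    if all(np.isscalar(s) for s in sizes):
        sizes = DEFAULT_ENSEMBLE_WIDTH_RANGES
    members = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_members)):
        cfg = replace(base_config, hidden_layer_sizes=sizes, seed=_child_seed(child))
        model = train_fixture_classifier(features, labels, cfg, vary_depth=True)
        model.meta["member"] = i
        members.append(model)
    return members
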