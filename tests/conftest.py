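"""Shared fixtures: tiny classifier doubles and a trained fixture model."""

import numpy as np
import pytest

from uqeval import (FixtureModelConfig, LabeledPredictions, SyntheticTaskSpec,
                    generate_dataset, train_fixture_classifier)


class ConstantModel:
    """Classifier double emitting a fixed probability vector for every
    input; accepts stochastic calls but never varies (a model whose
    stochastic pathway is switched off)."""

    def __init__(self, probs, supports_stochastic=True):
        self.probs = np.asarray(probs, dtype=float)
        self.n_classes = len(self.probs)
        self.supports_stochastic = supports_stochastic

    def predict_proba(self, X, *, stochastic=False, rng=None):
        X = np.atleast_2d(X)
        return np.tile(self.probs, (len(X), 1))


class NoisyModel:
    """Stochastic double: deterministic base vector, Dirichlet jitter on
    stochastic calls.  Reproducible under a seeded generator."""

    def __init__(self, base=(0.7, 0.3), concentration=50.0):
        self.base = np.asarray(base, dtype=float)
        self.concentration = concentration
        self.n_classes = len(self.base)
        self.supports_stochastic = True

    def predict_proba(self, X, *, stochastic=False, rng=None):
        X = np.atleast_2d(X)
        if not stochastic:
            return np.tile(self.base, (len(X), 1))
        rng = np.random.default_rng(rng)
        return rng.dirichlet(self.concentration * self.base, size=len(X))


@pytest.fixture
def constant_model():
    return ConstantModel([0.5, 0.5])


@pytest.fixture
def noisy_model():
    return NoisyModel()


@pytest.fixture(scope="session")
def small_task():
    """A modest two-Gaussian task at signal-to-noise 1 (Bayes error ~0.159)."""
    spec = SyntheticTaskSpec(n_samples=800, mean_separation=2.0, spread=1.0, seed=11)
    X, y = generate_dataset(spec)
    return spec, X, y


@pytest.fixture(scope="session")
def trained_model(small_task):
    """One dropout network trained quickly on the small task."""
    _, X, y = small_task
    config = FixtureModelConfig(epochs=60, seed=5)
    return train_fixture_classifier(X, y, config)


@pytest.fixture
def four_sample_lp():
    """The enumerated 4-sample example: at threshold 0.3 the outcome
    counts are TC=2, TU=1, FU=0, FC=1."""
    return LabeledPredictions(
        true_label=[0, 0, 1, 1],
        predicted_class=[0, 1, 1, 0],
        uncertainty=[0.10, 0.50, 0.20, 0.25],
        confidence=[0.95, 0.70, 0.90, 0.80],
        n_classes=2,
    )


def random_labeled_predictions(rng, n=None, n_classes=None) -> LabeledPredictions:
    """Random instance used by oracle-equivalence tests."""
    n = n or int(rng.integers(1, 51))
    n_classes = n_classes or int(rng.integers(2, 4))
    probs = rng.dirichlet(np.ones(n_classes), size=n)
    return LabeledPredictions(
        true_label=rng.integers(0, n_classes, n),
        predicted_class=probs.argmax(axis=1),
        uncertainty=rng.uniform(0, 1.6, n),
        confidence=probs.max(axis=1),
        n_classes=n_classes,
        probs=probs,
    )
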