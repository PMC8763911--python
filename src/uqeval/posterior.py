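"""Posterior approximation by stochastic forward passes and ensembling.

Exact Bayesian inference over network weights is intractable, so the
predictive posterior p(y | x) is approximated by sampling:

* **MC-dropout (MCD)** — keep dropout active at test time and average T
  stochastic forward passes; each pass evaluates the network under one
  sampled weight configuration.
* **Deep ensemble** — average the deterministic softmax outputs of N
  independently trained members.
* **EMCD** — run MC-dropout on every ensemble member and average the
  N x T draws.

All three produce a stack of per-draw class-probability vectors
(:class:`PosteriorSamples`); :func:`summarize_posterior` reduces the
stack to the posterior mean, the predicted class (argmax of the mean,
lowest index on exact ties), the confidence (max mean probability), the
predictive entropy of the mean, and the across-draw variance.

Seed policy: a master seed spawns one independent child stream per
(member, pass).  A stochastic pass draws its dropout masks once, at the
unit level, from that stream — one sampled weight configuration applied
to the whole batch — so results do not depend on how the batch is
partitioned across calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from ._utils import as_prob_array
from .errors import ContractViolationError, ValidationError
from .metrics import predictive_entropy

__all__ = [
    "StochasticClassifier",
    "PosteriorSamples",
    "PredictiveSummary",
    "mc_dropout_posterior",
    "ensemble_posterior",
    "ensemble_mc_dropout_posterior",
    "summarize_posterior",
    "DEFAULT_MC_PASSES",
]

#: default number of MC forward passes T
DEFAULT_MC_PASSES = 200


@runtime_checkable
class StochasticClassifier(Protocol):
    """Contract a classifier must satisfy to be sampled from.

    ``predict_proba(X, stochastic=..., rng=...)`` returns an (N, C) array
    of class probabilities; every row sums to 1 within 1e-6.  With
    ``stochastic=False`` repeated calls on the same inputs are identical.
    With ``stochastic=True`` and a fixed ``rng`` seed the call is
    reproducible; ``supports_stochastic`` is True iff repeated stochastic
    calls can differ (e.g. dropout active at inference).
    """

    n_classes: int
    supports_stochastic: bool

    def predict_proba(self, X, *, stochastic: bool = False, rng=None) -> np.ndarray:
        ...


@dataclass
class PosteriorSamples:
    """Stack of per-draw class-probability vectors for a batch of inputs.

    ``samples`` has shape (S, N, C): S draws (T MC passes, ensemble
    members, or members x passes), N inputs, C classes.  ``draw_labels``
    names each draw (pass and/or member index); ``source`` is one of
    ``"mcd"``, ``"ensemble"``, ``"emcd"``.
    """

    samples: np.ndarray
    draw_labels: list[str]
    source: str
    seed: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValidationError("samples must have shape (S, N, C)")
        s, _, c = self.samples.shape
        if s < 1 or c < 2:
            raise ValidationError("need S >= 1 draws and C >= 2 classes")
        if len(self.draw_labels) != s:
            raise ValidationError("draw_labels length must equal the number of draws")
        if self.source not in ("mcd", "ensemble", "emcd"):
            raise ValidationError(f"unknown source {self.source!r}")
        as_prob_array(self.samples, name="samples")

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    def save(self, path) -> None:
        """Write a compressed array archive plus a JSON sidecar with the
        draw labels, source and seed."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), samples=self.samples)
        sidecar = {"draw_labels": self.draw_labels, "source": self.source,
                   "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as npz:
            samples = npz["samples"]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(samples=samples, **sidecar)


@dataclass
class PredictiveSummary:
    """Per-sample reduction of a posterior sample stack."""

    mean_probs: np.ndarray          # (N, C)
    predicted_class: np.ndarray     # (N,) int
    confidence: np.ndarray          # (N,) max mean probability
    entropy: np.ndarray             # (N,) predictive entropy of the mean
    entropy_base: float
    per_sample_variance: np.ndarray  # (N, C) variance across draws


def _spawn_generators(seed: int | None, k: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(k)]


def _collect_draws(calls) -> np.ndarray:
    draws = [as_prob_array(d, name="model output") for d in calls]
    return np.stack(draws, axis=0)


def mc_dropout_posterior(model: StochasticClassifier, inputs, T: int = DEFAULT_MC_PASSES,
                         seed: int | None = 0) -> PosteriorSamples:
    """Approximate the posterior of one model by T stochastic passes.

    Each pass t evaluates the model with dropout active under an
    independent child stream of ``seed``; the draws are stored (not
    streamed) so the posterior mean can be re-derived from them exactly.
    """
    if T < 1:
        raise ValidationError(f"T must be >= 1, got {T}")
    if not getattr(model, "supports_stochastic", False):
        raise ContractViolationError(
            "model.supports_stochastic is False: MC-dropout needs a classifier "
            "whose stochastic forward passes can differ")
    rngs = _spawn_generators(seed, T)
    samples = _collect_draws(
        model.predict_proba(inputs, stochastic=True, rng=rngs[t]) for t in range(T))
    labels = [f"pass={t}" for t in range(T)]
    return PosteriorSamples(samples=samples, draw_labels=labels, source="mcd", seed=seed)


def _check_members(models: Sequence[StochasticClassifier]) -> int:
    if len(models) == 0:
        raise ValidationError("ensemble needs at least one member")
    n_classes = {m.n_classes for m in models}
    if len(n_classes) != 1:
        raise ValidationError(f"ensemble members disagree on n_classes: {sorted(n_classes)}")
    return n_classes.pop()


def ensemble_posterior(models: Sequence[StochasticClassifier], inputs) -> PosteriorSamples:
    """One deterministic draw per ensemble member; the member-mean softmax
    is the predictive distribution."""
    _check_members(models)
    samples = _collect_draws(
        m.predict_proba(inputs, stochastic=False) for m in models)
    labels = [f"member={i}" for i in range(len(models))]
    return PosteriorSamples(samples=samples, draw_labels=labels, source="ensemble")


def ensemble_mc_dropout_posterior(models: Sequence[StochasticClassifier], inputs,
                                  T: int = DEFAULT_MC_PASSES,
                                  seed: int | None = 0) -> PosteriorSamples:
    """MC-dropout on every ensemble member: N x T draws, grand mean as
    the posterior.  Draw order is member-major; the (member i, pass t)
    draw uses child stream i*T + t of the master seed, so a one-member
    EMCD reproduces plain MC-dropout bit for bit.

    A member without stochastic support degenerates gracefully: its T
    draws are the single deterministic output repeated, so an ensemble
    of deterministic members reduces draw-by-draw to
    :func:`ensemble_posterior`."""
    if T < 1:
        raise ValidationError(f"T must be >= 1, got {T}")
    _check_members(models)
    rngs = _spawn_generators(seed, len(models) * T)
    draws, labels = [], []
    for i, m in enumerate(models):
        if getattr(m, "supports_stochastic", False):
            member_draws = [m.predict_proba(inputs, stochastic=True, rng=rngs[i * T + t])
                            for t in range(T)]
        else:
            member_draws = [m.predict_proba(inputs, stochastic=False)] * T
        draws.extend(member_draws)
        labels.extend(f"member={i}/pass={t}" for t in range(T))
    return PosteriorSamples(samples=_collect_draws(draws), draw_labels=labels,
                            source="emcd", seed=seed)


def summarize_posterior(ps: PosteriorSamples, entropy_base: float = 2.0) -> PredictiveSummary:
    """Reduce a sample stack to per-sample posterior statistics.

    The predictive entropy is computed from the posterior-mean vector
    (base 2 by default, so binary entropy spans [0, 1]); the per-class
    variance across draws is the classical "predictive uncertainty"
    spread of the sampled distribution.
    """
    mean = ps.samples.mean(axis=0)
    mean = mean / mean.sum(axis=1, keepdims=True)  # remove accumulated roundoff
    ent = np.atleast_1d(predictive_entropy(mean, base=entropy_base))
    return PredictiveSummary(
        mean_probs=mean,
        predicted_class=np.argmax(mean, axis=1),
        confidence=mean.max(axis=1),
        entropy=ent,
        entropy_base=float(entropy_base),
        per_sample_variance=ps.samples.var(axis=0),
    )
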