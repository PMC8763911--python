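"""End-to-end synthetic uncertainty studies.

One study: draw a train and a test set from the two-Gaussian task, train
a single dropout network and a randomized-architecture ensemble, run the
three posterior approximations (MC-dropout, ensemble, EMCD) on the test
set, and evaluate each — test error against the task's closed-form Bayes
error, uncertainty confusion sweep, correct/incorrect entropy groups,
and calibration.

Every random choice (the two datasets, each model's training, the MC
pass streams) derives from a named child of the study's master seed, so
a study is reproducible from ``(config, seed)`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import DEFAULT_N_BINS, bin_predictions
from .io import EvaluationReport
from .metrics import (DEFAULT_THRESHOLD_GRID, LabeledPredictions,
                      group_uncertainty_summary, threshold_sweep)
from .posterior import (DEFAULT_MC_PASSES, ensemble_mc_dropout_posterior,
                        ensemble_posterior, mc_dropout_posterior, summarize_posterior)
from .synthetic import (FixtureModelConfig, SyntheticTaskSpec, bayes_error,
                        generate_dataset, make_fixture_ensemble,
                        train_fixture_classifier)

__all__ = ["StudyConfig", "MethodResult", "StudyResult", "run_study"]

METHODS = ("mcd", "ensemble", "emcd")


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the reference conditions: a binary task at
    signal-to-noise ``separation/(2 sigma) = 1`` (Bayes error ~0.159),
    1,600 training samples (split 75/25 inside the trainer), 2,000 test
    samples, dropout 0.25, T = 200 MC passes, a 30-member ensemble, the
    0.1-0.9 threshold grid and 10 calibration bins.
    """

    task: SyntheticTaskSpec = SyntheticTaskSpec(n_samples=1600)
    n_test: int = 2000
    model: FixtureModelConfig = FixtureModelConfig()
    n_members: int = 30
    mc_passes: int = DEFAULT_MC_PASSES
    methods: tuple[str, ...] = METHODS
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    n_bins: int = DEFAULT_N_BINS
    entropy_base: float = 2.0
    seed: int = 0


@dataclass
class MethodResult:
    """Evaluation of one posterior-approximation method on the test set."""

    method: str
    test_error: float
    predictions: LabeledPredictions
    report: EvaluationReport


@dataclass
class StudyResult:
    config: StudyConfig
    bayes_error: float
    methods: dict[str, MethodResult] = field(default_factory=dict)


def _sub_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def run_study(config: StudyConfig = StudyConfig()) -> StudyResult:
    """Run the full pipeline and evaluate every configured method."""
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    s_train_data, s_test_data, s_model, s_ensemble, s_mc = map(_sub_seed, seeds)

    train_spec = replace(config.task, seed=s_train_data)
    test_spec = replace(config.task, n_samples=config.n_test, seed=s_test_data)
    X_train, y_train = generate_dataset(train_spec)
    X_test, y_test = generate_dataset(test_spec)

    result = StudyResult(config=config, bayes_error=bayes_error(config.task))

    single = ensemble = None
    if "mcd" in config.methods:
        single = train_fixture_classifier(
            X_train, y_train, replace(config.model, seed=s_model))
    if {"ensemble", "emcd"} & set(config.methods):
        ensemble = make_fixture_ensemble(
            X_train, y_train, config.model, n_members=config.n_members, seed=s_ensemble)

    for method in config.methods:
        if method == "mcd":
            ps = mc_dropout_posterior(single, X_test, T=config.mc_passes, seed=s_mc)
        elif method == "ensemble":
            ps = ensemble_posterior(ensemble, X_test)
        elif method == "emcd":
            ps = ensemble_mc_dropout_posterior(
                ensemble, X_test, T=config.mc_passes, seed=s_mc)
        else:
            raise ValueError(f"unknown method {method!r}")
        summary = summarize_posterior(ps, entropy_base=config.entropy_base)
        lp = LabeledPredictions.from_summary(summary, y_test)
        report = EvaluationReport(
            sweep=threshold_sweep(lp, config.thresholds),
            calibration=bin_predictions(lp, config.n_bins),
            groups=group_uncertainty_summary(lp),
            metadata={
                "method": method,
                "seed": config.seed,
                "n_test": config.n_test,
                "mc_passes": config.mc_passes if method != "ensemble" else None,
                "n_members": config.n_members if method != "mcd" else None,
                "entropy_base": config.entropy_base,
                "bayes_error": result.bayes_error,
            },
        )
        result.methods[method] = MethodResult(
            method=method,
            test_error=1.0 - lp.accuracy,
            predictions=lp,
            report=report,
        )
    return result
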