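# Methods

## Posterior approximation

Exact Bayesian inference over the weights of a neural classifier is
intractable, so `uqeval` approximates the predictive posterior by
sampling, in three standard flavours:

* **MC-dropout (MCD).** Dropout is kept active at test time; each of T
  stochastic forward passes evaluates the network under one sampled
  weight configuration ω̂ₜ, and the predictive mean is
  μ_pred ≈ (1/T) Σₜ p(y = c | x, ω̂ₜ). T defaults to 200 passes.
* **Deep ensemble.** N independently trained members (default 30), each
  evaluated deterministically; the member-mean softmax is the posterior.
* **EMCD.** MC-dropout applied to every ensemble member; the posterior is
  the flat mean over all N×T draws.

The per-sample uncertainty score is the **predictive entropy** of the
posterior-mean vector, PE = −Σ_c p̂_c log p̂_c with the convention
0·log 0 = 0. The entropy of the *mean* (rather than the mean of per-draw
entropies) is used throughout: it captures both aleatoric spread within a
draw and disagreement between draws. The across-draw per-class variance
is also reported as the classical spread of the sampled distribution.

**Log base.** The entropy base defaults to 2, so binary PE spans [0, 1]
and the default threshold grid 0.1–0.9 covers the full range; with the
natural log binary PE would cap at ln 2 ≈ 0.693 and thresholds above 0.7
would be vacuous. The base is configurable everywhere (`entropy_base`).

**Seed policy.** A master seed spawns one independent child stream per
(member, pass) via `numpy.random.SeedSequence`. A stochastic pass draws
its dropout masks once, at the unit level, and applies them to the whole
batch — i.e. one sampled weight configuration per pass — so posterior
samples are invariant to how a batch is partitioned across calls, and a
one-member EMCD is bit-identical to plain MCD under the same seed. Draws
are stored as an (S, N, C) stack rather than streamed; at the scales this
package targets the memory cost is irrelevant and the stored stack lets
tests re-derive every summary by brute force.

**Degenerate members.** The EMCD routine evaluates a member that does not
support stochastic passes deterministically and repeats that draw T
times, so an ensemble of deterministic members reduces draw-by-draw to
the plain ensemble posterior. Plain MCD on a non-stochastic model is
instead a contract violation (the result would misrepresent a point
estimate as a posterior), raised as an explicit error naming the
`supports_stochastic` flag.

**Ties.** The predicted class is the argmax of the posterior mean with
ties resolved to the lowest class index. Ties have measure zero for real
posteriors but appear in symmetric synthetic fixtures, so the rule is
fixed and documented.

## Uncertainty confusion matrix

Each prediction is *correct* or *incorrect* against the ground truth,
and *certain* or *uncertain* by comparing its uncertainty score with a
threshold. A prediction is uncertain **iff its score strictly exceeds
the threshold**; ties count as certain. Strict inequality makes
"threshold at the maximum attainable entropy ⇒ nothing flagged" an exact
identity. The four cells are TC (correct∧certain), TU
(incorrect∧uncertain), FU (correct∧uncertain) and FC
(incorrect∧certain), and the metrics are USen = TU/(TU+FC),
USpe = TC/(TC+FU), UPre = TU/(TU+FU), UAcc = (TU+TC)/n.

A zero denominator (e.g. USen on an error-free batch) yields `nan`, an
explicit undefined marker that reports serialise as an empty CSV cell or
JSON `null` — never 0 or 1, which would silently inflate or deflate
scores on perfect batches.

Two identities follow from the definitions and are asserted as
invariants: TC+TU+FU+FC = n at every threshold, and (TC+FU)/n equals
ordinary classification accuracy (the threshold only re-partitions each
correctness group). Because raising the threshold shrinks the flagged
set by set inclusion, USen is non-increasing and USpe non-decreasing in
the threshold; UPre and UAcc typically rise on accurate models but that
is an empirical pattern, not a theorem, and is only checked on the
synthetic study.

The threshold grid defaults to 0.1–0.9 in steps of 0.1, with 0.3 as the
highlighted single-threshold report. The uncertainty score is pluggable:
any non-negative per-sample score in a prediction table is accepted, so
the metrics apply to arbitrary probabilistic forecasts.

## Calibration

Confidence is the max of the posterior-mean softmax vector. Predictions
are grouped into M equal-width bins on [0, 1] (left-open right-closed,
sample with confidence p in bin ⌈pM⌉, p = 0 in the first bin; M defaults
to 10, the common reliability-diagram choice). Per-bin accuracy is the
fraction of correct predictions, per-bin confidence the mean
max-probability, and ECE = Σₘ (|Bₘ|/n)·|acc(Bₘ) − conf(Bₘ)|. Empty bins
carry weight zero and are reported as undefined. ECE is reported both as
a fraction and ×100 (`ece_percent`), matching the percent scale used in
printed comparisons. Only evaluation is provided; recalibration
(temperature scaling etc.) is out of scope.

## Synthetic tasks and the fixture network

The generator draws two classes from isotropic Gaussians at distance Δ
along the first feature axis (spread σ, default 2 features, equal
priors; an imbalanced 0.25/0.75 preset is available). Isotropic
Gaussians were chosen because the equal-prior case has the closed-form
Bayes error Φ(−Δ/(2σ)) — an analytic anchor no private imaging dataset
can offer. The default study condition is Δ/(2σ) = 1, i.e. ~15.9%
irreducible error: hard enough that every posterior method faces a
substantial misclassified group, easy enough that accuracy is clinically
plausible. What the generator does *not* emulate: image structure,
label noise, covariate shift, class-dependent difficulty. Passing tests
therefore show the machinery is correct and that entropy separates
errors from correct predictions when mistakes cluster near a decision
boundary — not that any particular imaging model is well calibrated.

The fixture classifier is a compact fully connected network (ReLU,
softmax head) with inverted dropout on the hidden layers, trained by
Adam on cross-entropy. It is implemented directly on numpy arrays so
that dropout remains available at inference, which the MC-dropout
contract requires. Defaults: hidden layers 32/16, dropout 0.25, 200
epochs, learning rate 1e-3, batch size 128, and an internal 75/25
train/validation split (validation accuracy is recorded in the model
metadata). Ensemble members draw 2–3 hidden layers with widths from the
per-layer ranges (16–64, 8–32, 4–16); these desk-scale sizes keep a full
30-member, 30-seed study in the minutes range on one CPU while leaving
larger widths one config field away. All randomness — architecture
draw, initialisation, split, shuffling, dropout masks — derives from
named sub-streams of the config seed.

## Numerical choices

* Probability vectors must sum to 1 within 1e-6 internally; prediction
  tables read from text are accepted at 1e-4 and renormalised, so text
  round-tripping cannot invalidate a table.
* Entropy values are clipped at 0 from below to absorb −0 roundoff on
  one-hot vectors; the posterior mean is renormalised after averaging.
* CSV reports print 4 significant digits; JSON keeps full precision;
  CSV reading uses round-trip float parsing so computed columns survive
  export/import bit-exactly.
* The ECE identity Σ (|Bₘ|/n)|acc−conf| is maintained to 1e-12 by
  construction and asserted in tests.

## Study scale

The packaged end-to-end study trains on 1,600 samples (1,200 after the
split) and evaluates on 2,000 held-out points with T = 200 MC passes and
30 ensemble members. The multi-seed recovery checks use 30 independent
study seeds and test three properties per method: median test error
within 0.05 of the Bayes error; a positive misclassified-minus-correct
mean-entropy gap in at least 27 of 30 seeds; and the existence of a grid
threshold whose across-seed median USen ≥ 0.7 with median USpe ≥ 0.5.
The gap and flagging thresholds are engineering choices for an
automated check of a qualitative claim, not estimates of any real
dataset's effect size.

## Known limitations

* The fixture network is deliberately small; it demonstrates the
  contract, it is not a competitive classifier. Real models (CNNs,
  gradient-boosted trees with probability jitter, ...) plug in through
  `StochasticClassifier`.
* `bayes_error` covers the equal-prior isotropic case only and raises
  otherwise.
* Ensembles are trained sequentially; there is no parallel training.
* No plotting: sweeps, group summaries and reliability tables are
  emitted as tidy tables for any plotting layer to consume.
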