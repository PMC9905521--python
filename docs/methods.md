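# Methods

## The generator

`dynsig` synthesizes labelled univariate and multivariate time series from a
fixed registry of 15 small continuous-time dynamical systems, spanning four
behaviour classes:

| class | models | dims |
|---|---|---|
| chaotic | Ueda (CHA_1), Lorenz (CHA_2), Rössler (CHA_3), Halvorsen (CHA_4), Rucklidge (CHA_5) | 2,3,3,3,3 |
| periodic | two undamped (OSC_1/2), two damped (DOSC_1/2), one rising (IOSC) linear oscillator | 2 each |
| quasi-periodic | three explicit two-tone signals (QPS_1/2/3) | 1 each |
| non-periodic | two stable linear systems (DS_1/2) | 3 each |

State dimensions sum to 33, so the default build (1,000 runs per model,
1,000 samples per run) yields 15,000 CSV files containing 33,000 univariate
series.

**Initial-condition augmentation.** Every run scales each element of the
model's canonical initial state x₀ by an independent draw of 2·rand()−1
with rand uniform on (0, 1); elements that are zero stay zero, and each
randomized element lies in (−|x₀ᵢ|, |x₀ᵢ|). The quasi-periodic models apply
the same rule to their scalar canonical phase 2π, giving phases uniform on
(−2π, 2π).

**Integration and resampling.** ODE-form models are integrated with the
adaptive Runge–Kutta(4,5) pair (`scipy.integrate.solve_ivp`, `RK45`) at
relative/absolute tolerances 1e−3 / 1e−6 (the classic defaults of that
solver family; both are config-exposed), then resampled at the equidistant
grid tᵢ = i·T_max/(s−1), i = 0…s−1, inclusive of both endpoints. Resampling
uses the solver's own continuous extension by default; cubic-spline and
linear interpolation over the accepted steps are available as config
options and agree with the dense output to well below the solver tolerance.
The three quasi-periodic signals are evaluated directly on the grid.
A run whose integration fails or leaves the finite range raises a
divergence error naming the model and initial condition; such runs are
retried with a fresh randomized IC up to 10 times. With the registry's
canonical states no retries occur — all fifteen systems are bounded on
their printed horizons.

**Determinism.** One master seed derives a per-(model, run, stream) child
seed through `numpy.random.SeedSequence([master, model_index, run_index,
stream])`; the training pool and the held-out pool use different stream
tags. Every output byte is a pure function of (master seed, config,
registry), and any single run is regenerable in isolation from its recorded
child seed. Run files store values in the shortest decimal form that
round-trips to the same float64, so regenerated trees are byte-identical
across platforms.

## The phase-portrait embedding

For a univariate signal the pseudo-state-space (x, x′, x″) is built with
second-order central differences on interior points:
x′ᵢ = (xᵢ₊₁−xᵢ₋₁)/(2Δt), x″ᵢ = (xᵢ₊₁−2xᵢ+xᵢ₋₁)/Δt². The stencil of the
original embedding code is not published; the standard second-order scheme
is used and tested against analytic derivatives (error O(Δt²)). No
smoothing is applied.

## The validation experiments

Each state variable of each run is treated as an independent univariate
signal. Signals are cut into contiguous, non-overlapping segments of
Y ∈ {50, 100, 200} samples from the start of the series; segments are the
classification units, chaotic-model segments forming the positive class.

* **Experiment 1** uses all segments of the seven-model subset
  (CHA_1/2/3 vs OSC_1, DOSC_2, IOSC, DS_1).
* **Experiment 2** is identical but keeps only each signal's first segment.
* **Experiment 3** evaluates the trained models on the test set augmented
  with every quasi-periodic segment of the held-out pool, labelled
  non-chaos — probing the hypothesis that quasi-periodic signals resemble
  chaotic ones closely enough to hurt the classifiers.

**Splits and balancing.** Runs are assigned 75%/25% to train/validation at
the run level per model, so all signals (and hence all segments) of a run
share one set and there is no leakage. The test set comes from an
independently seeded hold-out batch whose size defaults to 74% of the
training pool — the published test/train signal proportion, whose exact
derivation was never released. Classes are counterbalanced by uniform
random down-sampling of majority-class signals within each set, with the
balancing seed in the split seed.

## The classifiers

Two small architectures operate on raw (unnormalized) length-Y segments:

* **LSTM**: input (batch, Y, 1) → LSTM with 4 units → dropout 0.5 →
  2-unit dense output with sigmoid activation. 106 trainable parameters.
* **CNN**: one block of Conv1D (32 filters, kernel 3, valid padding) →
  ReLU → batch normalization → dropout 0.5, then flatten → 2-unit dense
  sigmoid. The deep variant (used with first-segment training, where the
  single-block model underfits) stacks three blocks with 32/64/64 filters.

Both train with categorical cross-entropy, Adam at learning rate 0.001 and
batch size 64. The 2-unit *sigmoid* head with one-hot targets is the
architecture as printed; the cross-entropy therefore normalizes the two
sigmoid activations to a distribution before the log, reproducing the
usual framework semantics of that pairing. A softmax head is available
behind `ClassifierConfig(head="softmax")`.

The layers and optimizer are implemented in numpy inside the package
(`dynsig.nn`): LSTM with Glorot/orthogonal init and unit forget-gate bias,
valid 1-D convolution, batch normalization (momentum 0.99, ε = 1e−3),
inverted dropout, and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−7). Gradients are
verified against central finite differences in the test suite, and training
is bit-deterministic given `train_seed`.

**Epochs.** No epoch budget was published; the `ClassifierConfig` default
is 30 epochs with early stopping on validation loss (patience 5) and
restoration of the best validation-loss weights, all config-exposed.
The benchmark driver (`dynsig.benchmark`, used by `reproduce-all` and the
acceptance script) overrides this with plain fixed-epoch training — see
the desk-scale section below.

**Speed.** The LSTM recurrence and the batch-norm statistics also have
numba-compiled kernels (`dynsig._kernels`) implementing arithmetic
identical to the numpy reference paths; the tests assert the two paths
agree to floating-point noise, and the package falls back to pure numpy
when numba is unavailable.

## Desk-scale study sizes

The classifier reproductions run at 100 runs/model (training pool) and
74 runs/model (held-out pool) — the package's desk-scale default — rather
than the full 1,000. Full scale is supported (`dynsig reproduce-all
--runs 1000 --test-runs 740`). Two consequences of scale are handled
explicitly:

* Desk-scale training sets are 10–200× smaller than full scale, so a fixed
  30-epoch schedule under-trains (most severely for the first-segment sets
  and for Y = 200, which have the fewest segments). The benchmark driver
  therefore guarantees a minimum optimization budget of ~6,000 Adam
  updates per training run — the full-scale first-segment budget — by
  raising the epoch cap inversely with the training-set size, and trains
  to the cap without early stopping: at this scale the validation set is
  small and its loss too noisy to be a reliable stopping signal, and
  stopping on it strands the Y = 200 models well short of convergence.
  Instead, validation accuracy is monitored every 2nd epoch and the
  best-validation-accuracy checkpoint is restored at the end, which also
  guards against occasional late-training collapse of the tiny LSTM.
  The `epochs`, `min_updates`, `restore_best` and `validation_freq` knobs
  expose all of this.
* Stochastic accuracy checks aggregate over three training seeds
  (majority vote for the ≥95% bound, seed-averaged means for point
  values).

## What the synthetic data does and does not show

The generator reproduces the benchmark's study conditions exactly: the same
fifteen systems, parameterizations, canonical states, horizons and
augmentation rule. It does not model measurement noise, missing samples,
nonstationary sampling rates, or any physiological signal properties — a
classifier that separates these clean classes has demonstrated only that
the dataset is learnable, not that it detects chaos in real biomedical
recordings. Amplitude is an honest but partly confounding cue here: the
chaotic attractors evolve at larger amplitudes than most of the linear
oscillators, and nothing in the published protocol normalizes segments.

## Numerical choices and limitations

* β = 8/3 of the Lorenz system is stored as the double nearest to the
  exact rational.
* The Ueda oscillator's forcing uses the literal integrator time, not a
  wrapped phase.
* Ties in the 2-class argmax resolve to the non-chaos class (index 0);
  with continuous sigmoid scores exact ties do not occur in practice.
* Linear-model trajectories are tested against an independent
  matrix-exponential oracle (1e−2 for oscillatory, 1e−3 for damped
  non-oscillatory models at the default solver tolerances); the undamped
  oscillators conserve x₁²+x₂² to better than 1% relative over the full
  horizon.
* At desk scale the quasi-periodic stress test loses some of its bite for
  long segments: a 200-sample window exposes the two-tone structure so
  clearly that the classifiers label quasi-periodic signals correctly,
  and because the desk-scale base accuracy sits near 0.96 (not the
  full-scale 0.98+), appending these easy negatives can *raise* test
  accuracy by up to (1−accuracy)·(QPS share) ≈ 0.006 — slightly more than
  the ≤0.005 rise the full-scale benchmark exhibits. The corresponding
  check in the test suite documents this as a known desk-scale deviation
  (it fails for the CNN at Y = 200); at Y ∈ {50, 100} the degradation
  reproduces, most clearly for the CNN at Y = 100.
* The published test-pool sizes (12,652 / 15,652 / 15,655 signals) are not
  derivable from the described protocol and are internally inconsistent;
  this package fixes the hold-out proportion at 74% instead and makes no
  attempt to match those counts.
* Exact byte-level reproduction of the originally deposited CSV archives is
  impossible (their RNG state was never published); format, shapes and
  counts match.
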