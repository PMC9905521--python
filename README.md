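# dynsig

Synthetic time-series benchmark for learning the qualitative character of
dynamical systems — in particular, for training and evaluating detectors of
**chaos** in univariate signals.

Whether a measured signal is chaotic matters in biomedical signal analysis:
local dynamic stability of gait, eye-movement dynamics during fixations, and
the long-debated nonlinear structure of PPG/ECG/HRV recordings are all
framed in terms of sensitivity to initial conditions. Classical indicators
(largest Lyapunov exponent, correlation dimension) are noise-sensitive, and
learning-based detectors need large labelled corpora of signals whose
dynamics are known by construction. `dynsig` generates exactly that corpus
and ships the baseline classifiers that validate it.

## What it generates

A registry of 15 small continuous-time systems in four behaviour classes:

* 5 **chaotic** dissipative flows — Ueda, Lorenz, Rössler, Halvorsen,
  Rucklidge (e.g. Lorenz: ẋ₁ = −σx₁+σx₂, ẋ₂ = ρx₁−x₂−x₁x₃, ẋ₃ = −βx₃+x₁x₂
  with σ = 10, β = 8/3, ρ = 28);
* 5 **periodic** linear oscillators (undamped, damped, rising);
* 3 **quasi-periodic** explicit two-tone signals with irrational frequency
  ratio (π, golden ratio, e), e.g. x = cos(ω₁t/50+x₀) + cos(t/50+x₀);
* 2 **non-periodic** stable linear systems with fading solutions.

Each run randomizes the canonical initial state x₀ element-wise by
independent uniform (−1, 1) factors, integrates with adaptive RK45 over
[0, T_max] and resamples 1,000 equidistant points (explicit signals are
evaluated directly). At the default 1,000 runs per model this yields 15,000
headerless CSV files — one column per state variable — containing 33,000
labelled univariate series, plus a manifest of every seed and initial
condition, byte-reproducible from the master seed.

The baseline task is binary: chaos (positive) vs non-chaos, on raw segments
of Y ∈ {50, 100, 200} samples, with two small classifiers — an LSTM
(4 units → dropout 0.5 → 2-unit sigmoid dense) and a 1-D CNN
(Conv1D 32×3 → ReLU → batch norm → dropout → dense) — trained with
categorical cross-entropy, Adam (lr 0.001), batch 64. Both are implemented
in numpy inside the package with finite-difference-verified gradients and
seed-deterministic training. See `docs/methods.md` for the full protocol.

## Worked example

Generate a few runs of two models and inspect them:

```sh
$ dynsig generate --model OSC_1 --model CHA_2 --runs 3 --samples 1000 --seed 42 --out data
6 files, 15 series -> data
$ head -2 data/CHA_2_0000.csv
1.3427416153159455,7.8421666881284935,-5.474249003693612
9.39225846862154,21.153140821072487,2.5070084579472955
```

Six files: three 1000×2 runs of the undamped oscillator and three 1000×3
Lorenz runs (2·3 + 3·3 = 15 univariate series). Each Lorenz run starts from
a randomized point in (−10,10)×(−200,200)×(−10,10) and settles onto the
attractor.

```python
>>> from dynsig import GeneratorConfig, get_model, integrate
>>> m = get_model("CHA_2")
>>> traj = integrate(m, m.x0, GeneratorConfig())
>>> traj.values.shape
(1000, 3)
>>> # x1 stays on the attractor: range [-27.5, 24.1]
>>> from dynsig.experiments import ConfusionCounts
>>> ConfusionCounts(tp=107_389, fn=5_651, tn=139_992, fp=8).accuracy
0.9776...
```

The last line recomputes a published benchmark row: 253,040 test segments
of length 50, of which the LSTM mislabelled 5,651 chaotic and 8 non-chaotic
ones — accuracy 0.978.

Run one validation experiment end to end (desk scale) and draw a
phase portrait:

```sh
dynsig experiment --exp 1 --length 100 --arch lstm --runs 100 --out exp1_lstm100
dynsig portrait --file data/OSC_1_0000.csv --out portrait.png
dynsig reproduce-all --runs 100 --out reports   # all 3 experiments × 2 archs × 3 Y
```

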