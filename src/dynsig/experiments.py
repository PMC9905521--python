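"""Assembly of the chaos-vs-non-chaos validation experiments.

Each multidimensional run contributes every state variable as an independent
univariate signal; signals are cut into contiguous fixed-length segments
(Y ∈ {50, 100, 200} samples) which are the classification units.  Chaotic
models form the positive class, everything else the negative class.

Three experiments are defined over a seven-model subset (three chaotic:
Ueda, Lorenz, Rössler; four non-chaotic: undamped oscillator 1, damped
oscillator 2, rising oscillator, damped system 1):

1. all segments of every signal;
2. identical, but only the first segment of each signal;
3. the experiment-1 (or -2) split with the test set augmented by all
   quasi-periodic segments, labelled non-chaos — probing whether
   quasi-periodic signals, superficially similar to chaotic ones, degrade
   the classifiers.

Classes are counterbalanced by uniform down-sampling of the majority class
at the whole-signal level; the train pool is split 75%/25% into train and
validation at the run level, so segments of one run never straddle sets.
The test set comes from an independently seeded hold-out batch of runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .models import BehaviourClass, get_model

__all__ = [
    "CHAOS", "NON_CHAOS",
    "SegmentConfig", "LabelledSegmentSet", "ConfusionCounts", "ExperimentSplit",
    "EXPERIMENT_MODELS", "QPS_MODELS",
    "label_for", "segment", "build_experiment", "confusion",
    "pool_signal_count", "segment_count",
]

CHAOS = 1
NON_CHAOS = 0

#: seven-model subset used by all three validation experiments
EXPERIMENT_MODELS: tuple[str, ...] = (
    "CHA_1", "CHA_2", "CHA_3", "OSC_1", "DOSC_2", "IOSC", "DS_1",
)
QPS_MODELS: tuple[str, ...] = ("QPS_1", "QPS_2", "QPS_3")

TRAIN_FRACTION = 0.75  # remainder is validation


def label_for(symbol: str) -> int:
    """Binary label from a model's behaviour class; chaos is positive."""
    spec = get_model(symbol)
    return CHAOS if spec.behaviour_class is BehaviourClass.CHAOTIC else NON_CHAOS


@dataclass(frozen=True)
class SegmentConfig:
    """Segment length Y and whether all segments or only the first are used."""

    length: int = 100
    mode: str = "all_segments"  # "all_segments" | "first_segment_only"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("segment length must be positive")
        if self.mode not in ("all_segments", "first_segment_only"):
            raise ValueError(f"unknown segment mode {self.mode!r}")


@dataclass
class LabelledSegmentSet:
    """Fixed-length segments with binary labels and source bookkeeping.

    ``sources[i]`` is (model_symbol, run_index, variable_index, segment_index).
    """

    X: np.ndarray  # (n, Y)
    y: np.ndarray  # (n,) int8, 1 = chaos
    sources: list[tuple[str, int, int, int]]

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == CHAOS))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y == NON_CHAOS))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with the chaos class as positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass
class ExperimentSplit:
    train: LabelledSegmentSet
    validation: LabelledSegmentSet
    test: LabelledSegmentSet


def segment(series: Sequence[float], cfg: SegmentConfig) -> list[np.ndarray]:
    """Cut a series into contiguous non-overlapping windows from the start.

    Returns floor(s/Y) windows (exactly s/Y at the benchmark defaults where Y
    divides s = 1,000), or just window 0 in first_segment_only mode.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be univariate")
    y = cfg.length
    if y > x.size:
        raise ValueError(f"segment length {y} exceeds series length {x.size}")
    n = x.size // y
    if cfg.mode == "first_segment_only":
        n = 1
    return [x[i * y:(i + 1) * y] for i in range(n)]


def _signal_keys(pool: Mapping[str, np.ndarray], symbols: Sequence[str],
                 runs: Mapping[str, Sequence[int]] | None = None):
    """Enumerate (symbol, run, var) univariate signals of a trajectory pool."""
    keys = []
    for sym in symbols:
        if sym not in pool:
            raise KeyError(f"model {sym} missing from dataset pool")
        arr = pool[sym]
        run_idx = range(arr.shape[0]) if runs is None else runs[sym]
        for r in run_idx:
            for v in range(arr.shape[2]):
                keys.append((sym, int(r), v))
    return keys


def _balance(keys: list[tuple[str, int, int]], rng: np.random.Generator):
    """Counterbalance classes by down-sampling majority-class signals."""
    pos = [k for k in keys if label_for(k[0]) == CHAOS]
    neg = [k for k in keys if label_for(k[0]) == NON_CHAOS]
    n = min(len(pos), len(neg))
    if len(pos) > n:
        pos = [pos[i] for i in sorted(rng.choice(len(pos), size=n, replace=False))]
    if len(neg) > n:
        neg = [neg[i] for i in sorted(rng.choice(len(neg), size=n, replace=False))]
    return pos + neg


def _materialize(pool: Mapping[str, np.ndarray], keys, cfg: SegmentConfig,
                 force_label: int | None = None) -> LabelledSegmentSet:
    X, y, sources = [], [], []
    for sym, run, var in keys:
        label = label_for(sym) if force_label is None else force_label
        for si, seg in enumerate(segment(pool[sym][run, :, var], cfg)):
            X.append(seg)
            y.append(label)
            sources.append((sym, run, var, si))
    Xa = np.asarray(X, dtype=float) if X else np.empty((0, cfg.length))
    return LabelledSegmentSet(Xa, np.asarray(y, dtype=np.int8), sources)


def build_experiment(
    exp_id: int,
    train_pool: Mapping[str, np.ndarray],
    test_pool: Mapping[str, np.ndarray],
    cfg: SegmentConfig,
    split_seed: int,
) -> ExperimentSplit:
    """Assemble train/validation/test labelled segment sets for one experiment.

    ``train_pool`` and ``test_pool`` map model symbol → (runs, s, dim) arrays;
    the test pool must come from an independently seeded generation batch.
    Experiment 2 forces first_segment_only mode; experiment 3 reuses the
    experiment-1/-2 split (per ``cfg.mode``) and appends every quasi-periodic
    segment of the test pool to the test set with the non-chaos label.
    """
    if exp_id not in (1, 2, 3):
        raise ValueError("exp_id must be 1, 2 or 3")
    if exp_id == 2:
        cfg = SegmentConfig(cfg.length, "first_segment_only")
    rng = np.random.default_rng(split_seed)

    # run-level 75/25 train/validation assignment, per model (hence stratified
    # by class); all signals of a run share its set
    train_runs: dict[str, list[int]] = {}
    val_runs: dict[str, list[int]] = {}
    for sym in EXPERIMENT_MODELS:
        if sym not in train_pool:
            raise KeyError(f"model {sym} missing from dataset pool")
        v = train_pool[sym].shape[0]
        order = rng.permutation(v)
        cut = int(round(TRAIN_FRACTION * v))
        train_runs[sym] = sorted(int(i) for i in order[:cut])
        val_runs[sym] = sorted(int(i) for i in order[cut:])

    train_keys = _balance(_signal_keys(train_pool, EXPERIMENT_MODELS, train_runs), rng)
    val_keys = _balance(_signal_keys(train_pool, EXPERIMENT_MODELS, val_runs), rng)
    test_keys = _balance(_signal_keys(test_pool, EXPERIMENT_MODELS), rng)

    train = _materialize(train_pool, train_keys, cfg)
    validation = _materialize(train_pool, val_keys, cfg)
    test = _materialize(test_pool, test_keys, cfg)

    if exp_id == 3:
        qps = _materialize(test_pool, _signal_keys(test_pool, QPS_MODELS), cfg,
                           force_label=NON_CHAOS)
        test = LabelledSegmentSet(
            np.vstack([test.X, qps.X]),
            np.concatenate([test.y, qps.y]),
            test.sources + qps.sources,
        )
    return ExperimentSplit(train, validation, test)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts over binary labels (chaos = positive)."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError("label arrays must have identical shape")
    return ConfusionCounts(
        tp=int(np.sum((t == CHAOS) & (p == CHAOS))),
        fn=int(np.sum((t == CHAOS) & (p == NON_CHAOS))),
        tn=int(np.sum((t == NON_CHAOS) & (p == NON_CHAOS))),
        fp=int(np.sum((t == NON_CHAOS) & (p == CHAOS))),
    )


def pool_signal_count(symbols: Sequence[str], runs_per_model: int) -> int:
    """Number of univariate signals a pool of runs contributes."""
    return sum(get_model(s).dim for s in symbols) * runs_per_model


def segment_count(n_signals: int, samples: int, cfg: SegmentConfig) -> int:
    """Segments produced from n signals of the given length."""
    per = 1 if cfg.mode == "first_segment_only" else samples // cfg.length
    return n_signals * per
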