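"""Trajectory generation: IC randomization, adaptive RK45 integration, resampling.

Every run of an ODE model starts from a randomized initial condition
(each element of the canonical x0 scaled by an independent uniform draw on
(−1, 1)), is integrated with an adaptive Runge–Kutta(4,5) scheme over
[0, T_max], and is resampled on the equidistant grid
t_i = i·T_max/(s−1), i = 0…s−1 (both endpoints included).  Explicit
quasi-periodic models randomize their scalar phase by the same rule and are
evaluated directly on the grid.

Randomness is hierarchical: one master seed deterministically derives a
per-(model, run) child seed, so any single run is regenerable in isolation
and the full dataset is byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .models import ModelSpec, explicit_value, registry, rhs

__all__ = [
    "GeneratorConfig",
    "Trajectory",
    "DivergenceError",
    "ManifestEntry",
    "GenerationManifest",
    "sample_times",
    "child_seed",
    "randomize_ic",
    "integrate",
    "evaluate_explicit",
    "simulate_run",
    "generate_dataset",
]

log = logging.getLogger(__name__)

#: stream tags separating the training pool from held-out test batches in the
#: seed derivation (same master seed, disjoint child streams)
TRAIN_STREAM = 0
TEST_STREAM = 1


@dataclass(frozen=True)
class GeneratorConfig:
    """Dataset-generation parameters.

    runs_per_model (v) and samples (s) default to the benchmark's 1,000 each;
    rel_tol/abs_tol are the adaptive-step error tolerances of the RK45 solver
    (the originating environment's defaults); interpolation selects how the
    solution is resampled onto the equidistant grid.
    """

    runs_per_model: int = 1000
    samples: int = 1000
    master_seed: int = 0
    rel_tol: float = 1e-3
    abs_tol: float = 1e-6
    interpolation: str = "dense"  # "dense" | "cubic" | "linear"
    retry_budget: int = 10

    def __post_init__(self) -> None:
        if self.runs_per_model < 1:
            raise ValueError("runs_per_model must be >= 1")
        if self.samples < 2:
            raise ValueError("samples must be >= 2")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.interpolation not in ("dense", "cubic", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


@dataclass(frozen=True)
class Trajectory:
    """One simulated run: equidistant times plus s×dim state values."""

    model_symbol: str
    run_index: int
    seed: int
    ic: np.ndarray
    times: np.ndarray
    values: np.ndarray  # shape (s, dim)

    @property
    def dim(self) -> int:
        return self.values.shape[1]


class DivergenceError(RuntimeError):
    """Raised when integration fails or produces non-finite state values."""

    def __init__(self, model: ModelSpec, ic: Sequence[float], detail: str) -> None:
        self.model_symbol = model.symbol
        self.ic = np.asarray(ic, dtype=float)
        super().__init__(
            f"integration of {model.symbol} diverged from ic={list(map(float, ic))}: {detail}"
        )


def sample_times(t_max: float, samples: int) -> np.ndarray:
    """Equidistant grid t_i = i·T_max/(s−1) including both endpoints."""
    return np.linspace(0.0, float(t_max), samples)


def child_seed(master_seed: int, model_index: int, run_index: int, stream: int = TRAIN_STREAM) -> int:
    """Deterministic per-run seed derived from (master, model, run, stream)."""
    ss = np.random.SeedSequence([int(master_seed), int(model_index), int(run_index), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def randomize_ic(x0: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Scale each element of x0 by an independent uniform draw on (−1, 1).

    Implements the augmentation rule 2·rand()−1 with rand uniform on (0, 1);
    zero elements of x0 stay exactly zero, and |result_i| <= |x0_i|.
    """
    x0 = np.asarray(x0, dtype=float)
    u = 2.0 * rng.random(x0.shape) - 1.0
    return x0 * u


def integrate(model: ModelSpec, ic: Sequence[float], config: GeneratorConfig) -> Trajectory:
    """Adaptive-step RK45 solution over [0, T_max], resampled equidistantly.

    Deterministic given (model, ic, config).  Raises :class:`DivergenceError`
    when the solver fails or the state leaves the finite range.
    """
    if model.form != "ode":
        raise ValueError(f"{model.symbol} is explicit; use evaluate_explicit")
    ic = np.asarray(ic, dtype=float)
    times = sample_times(model.t_max, config.samples)

    fun = lambda t, x: rhs(model, t, x)  # noqa: E731
    kwargs = dict(method="RK45", rtol=config.rel_tol, atol=config.abs_tol)
    if config.interpolation == "dense":
        sol = solve_ivp(fun, (0.0, model.t_max), ic, t_eval=times, **kwargs)
        values = sol.y.T if sol.success else None
    else:
        sol = solve_ivp(fun, (0.0, model.t_max), ic, **kwargs)
        if sol.success:
            if config.interpolation == "cubic":
                values = CubicSpline(sol.t, sol.y, axis=1)(times).T
            else:
                values = np.column_stack([np.interp(times, sol.t, sol.y[d]) for d in range(model.dim)])
        else:
            values = None

    if values is None:
        raise DivergenceError(model, ic, sol.message)
    if not np.all(np.isfinite(values)):
        raise DivergenceError(model, ic, "non-finite state values")
    return Trajectory(model.symbol, -1, -1, ic, times, np.ascontiguousarray(values))


def evaluate_explicit(model: ModelSpec, phase: float, config: GeneratorConfig) -> Trajectory:
    """Sample an explicit quasi-periodic signal on the equidistant grid."""
    times = sample_times(model.t_max, config.samples)
    values = explicit_value(model, times, phase)[:, None]
    return Trajectory(model.symbol, -1, -1, np.array([phase]), times, values)


def simulate_run(
    model: ModelSpec,
    model_index: int,
    run_index: int,
    config: GeneratorConfig,
    stream: int = TRAIN_STREAM,
) -> tuple[Trajectory, int]:
    """Simulate one seeded run; returns (trajectory, number of IC retries).

    Divergent ODE runs are retried with a fresh randomized IC from the same
    child stream, up to ``config.retry_budget`` times.
    """
    seed = child_seed(config.master_seed, model_index, run_index, stream)
    rng = np.random.default_rng(seed)
    retries = 0
    while True:
        ic = randomize_ic(model.x0, rng)
        try:
            if model.form == "ode":
                traj = integrate(model, ic, config)
            else:
                traj = evaluate_explicit(model, float(ic[0]), config)
        except DivergenceError:
            retries += 1
            if retries > config.retry_budget:
                raise
            log.warning("retrying %s run %d after divergence (attempt %d)",
                        model.symbol, run_index, retries)
            continue
        return replace(traj, run_index=run_index, seed=seed), retries


@dataclass(frozen=True)
class ManifestEntry:
    model_symbol: str
    run_index: int
    seed: int
    ic: tuple[float, ...]
    path: str | None
    dim: int
    retries: int = 0


@dataclass
class GenerationManifest:
    """Machine-readable record of one dataset build."""

    master_seed: int
    runs_per_model: int
    samples: int
    entries: list[ManifestEntry] = field(default_factory=list)

    @property
    def n_files(self) -> int:
        return len(self.entries)

    @property
    def n_series(self) -> int:
        """Total univariate series: each state variable counts separately."""
        return sum(e.dim for e in self.entries)

    def models(self) -> list[str]:
        return sorted({e.model_symbol for e in self.entries})

    def to_records(self) -> list[dict]:
        return [
            {
                "model": e.model_symbol,
                "run": e.run_index,
                "seed": e.seed,
                "ic": list(e.ic),
                "path": e.path,
                "dim": e.dim,
                "retries": e.retries,
            }
            for e in self.entries
        ]


def generate_dataset(
    specs: Iterable[ModelSpec] | None,
    config: GeneratorConfig,
    sink=None,
    *,
    dry_run: bool = False,
    stream: int = TRAIN_STREAM,
) -> GenerationManifest:
    """Build the labelled dataset: runs_per_model seeded runs per model.

    ``sink`` is a dataset writer (see :mod:`dynsig.dataset_io`); with
    ``dry_run`` the manifest — seeds, randomized ICs, per-run paths and the
    series bookkeeping — is produced without integrating or writing anything.
    The registry index of a model (its position in symbol order over the full
    registry) anchors the seed derivation, so generating a subset of models
    yields the same trajectories as the full build.
    """
    full = registry()
    index_of = {m.symbol: i for i, m in enumerate(full)}
    specs = full if specs is None else sorted(specs, key=lambda m: m.symbol)

    manifest = GenerationManifest(config.master_seed, config.runs_per_model, config.samples)
    for model in specs:
        mi = index_of[model.symbol]
        for run in range(config.runs_per_model):
            if dry_run:
                seed = child_seed(config.master_seed, mi, run, stream)
                ic = randomize_ic(model.x0, np.random.default_rng(seed))
                path = sink.run_path(model.symbol, run) if sink is not None else None
                entry = ManifestEntry(model.symbol, run, seed, tuple(map(float, ic)),
                                      str(path) if path is not None else None, model.dim)
            else:
                traj, retries = simulate_run(model, mi, run, config, stream)
                path = None
                if sink is not None:
                    path = str(sink.write_run(traj).path)
                entry = ManifestEntry(model.symbol, run, traj.seed,
                                      tuple(map(float, traj.ic)), path, model.dim, retries)
            manifest.entries.append(entry)
    if sink is not None:
        sink.write_manifest(manifest)
    return manifest


def simulate_pool(
    specs: Iterable[ModelSpec],
    config: GeneratorConfig,
    stream: int = TRAIN_STREAM,
) -> dict[str, np.ndarray]:
    """In-memory dataset: symbol → array of shape (runs, s, dim).

    Convenience for the validation experiments, which consume trajectories
    directly rather than through CSV files.
    """
    full_index = {m.symbol: i for i, m in enumerate(registry())}
    pool: dict[str, np.ndarray] = {}
    for model in sorted(specs, key=lambda m: m.symbol):
        mi = full_index[model.symbol]
        runs = np.empty((config.runs_per_model, config.samples, model.dim))
        for run in range(config.runs_per_model):
            traj, _ = simulate_run(model, mi, run, config, stream)
            runs[run] = traj.values
        pool[model.symbol] = runs
    return pool
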