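"""Registry of the 15 benchmark dynamical systems.

The benchmark draws its signals from fifteen small continuous-time systems
spanning four behaviour classes:

* **chaotic** — five dissipative flows (Ueda, Lorenz, Rössler, Halvorsen,
  Rucklidge), each strongly sensitive to initial conditions;
* **periodic** — five linear oscillators (undamped, damped, rising);
* **quasi-periodic** — three explicit two-tone signals whose angular-frequency
  ratio is irrational (π, the golden ratio, e), so the signal never repeats;
* **non-periodic** — two stable linear systems with slowly fading,
  non-oscillatory solutions.

ODE-form models expose their right-hand side through :func:`rhs`; the three
quasi-periodic models are defined explicitly as functions of time and are
evaluated through :func:`explicit_value`.  State dimensions are 1–3 and sum
to 33 across the registry, which at 1,000 runs per model yields the 33,000
univariate series of the full dataset.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "BehaviourClass",
    "ModelSpec",
    "registry",
    "get_model",
    "rhs",
    "explicit_value",
    "registry_to_yaml",
]


class BehaviourClass(str, enum.Enum):
    """Qualitative long-run behaviour of a model; drives the chaos/non-chaos label."""

    CHAOTIC = "chaotic"
    PERIODIC = "periodic"
    QUASI_PERIODIC = "quasi-periodic"
    NON_PERIODIC = "non-periodic"


@dataclass(frozen=True)
class ModelSpec:
    """One benchmark system: equations, parameters, canonical IC and time horizon.

    ``x0`` is the canonical initial state; runs randomize it element-wise.
    For explicit (dim-1) models ``x0`` holds the single canonical phase 2π.
    ``t_max`` is the final value of the dimensionless independent variable t.
    """

    symbol: str
    name: str
    behaviour_class: BehaviourClass
    dim: int
    params: Mapping[str, float]
    x0: tuple[float, ...]
    t_max: float
    form: str  # "ode" | "explicit"
    equations: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.dim not in (1, 2, 3):
            raise ValueError(f"{self.symbol}: dim must be 1, 2 or 3")
        if (self.dim == 1) != (self.form == "explicit"):
            raise ValueError(f"{self.symbol}: dim-1 models must be explicit and vice versa")
        if len(self.x0) != self.dim:
            raise ValueError(f"{self.symbol}: x0 length {len(self.x0)} != dim {self.dim}")
        if self.t_max <= 0:
            raise ValueError(f"{self.symbol}: t_max must be positive")

    @property
    def is_chaotic(self) -> bool:
        return self.behaviour_class is BehaviourClass.CHAOTIC


_GOLDEN = (1.0 + math.sqrt(5.0)) / 2.0

_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec(
        "CHA_1", "Ueda oscillator", BehaviourClass.CHAOTIC, 2,
        {"b": 0.05, "A": 7.5, "Omega": 1.0}, (2.5, 0.0), 100.0, "ode",
        ("x1' = x2", "x2' = -x1^3 - b*x2 + A*sin(Omega*t)"),
    ),
    ModelSpec(
        "CHA_2", "Lorenz attractor", BehaviourClass.CHAOTIC, 3,
        {"sigma": 10.0, "beta": 8.0 / 3.0, "rho": 28.0}, (10.0, 200.0, 10.0), 100.0, "ode",
        ("x1' = -sigma*x1 + sigma*x2",
         "x2' = rho*x1 - x2 - x1*x3",
         "x3' = -beta*x3 + x1*x2"),
    ),
    ModelSpec(
        "CHA_3", "Rössler attractor", BehaviourClass.CHAOTIC, 3,
        {"a": 0.2, "b": 0.2, "c": 5.7}, (-9.0, 0.0, 0.0), 300.0, "ode",
        ("x1' = -x2 - x3", "x2' = x1 + a*x2", "x3' = b + x3*(x1 - c)"),
    ),
    ModelSpec(
        "CHA_4", "Halvorsen attractor", BehaviourClass.CHAOTIC, 3,
        {"a": 1.27}, (-5.0, 0.0, 0.0), 50.0, "ode",
        ("x1' = -a*x1 - 4*x2 - 4*x3 - x2^2",
         "x2' = -4*x1 - a*x2 - 4*x3 - x3^2",
         "x3' = -4*x1 - 4*x2 - a*x3 - x1^2"),
    ),
    ModelSpec(
        "CHA_5", "Rucklidge attractor", BehaviourClass.CHAOTIC, 3,
        {"k": 2.0, "lam": 6.7}, (1.0, 0.0, 4.5), 150.0, "ode",
        ("x1' = -k*x1 + lam*x2 - x2*x3", "x2' = x1", "x3' = -x3 + x2^2"),
    ),
    ModelSpec(
        "OSC_1", "Undamped oscillator 1", BehaviourClass.PERIODIC, 2,
        {"a": 0.5, "b": -0.5}, (1.0, 1.0), 100.0, "ode",
        ("x1' = a*x2", "x2' = b*x1"),
    ),
    ModelSpec(
        "OSC_2", "Undamped oscillator 2", BehaviourClass.PERIODIC, 2,
        {"a": 0.5, "b": -0.5}, (0.9, -0.9), 250.0, "ode",
        ("x1' = a*x2", "x2' = b*x1"),
    ),
    ModelSpec(
        "DOSC_1", "Damped oscillator 1", BehaviourClass.PERIODIC, 2,
        {}, (1.0, 1.0), 100.0, "ode",
        ("x1' = x2", "x2' = -0.2*x1 - 0.08*x2 + 0.01"),
    ),
    ModelSpec(
        "DOSC_2", "Damped oscillator 2", BehaviourClass.PERIODIC, 2,
        {}, (0.4, 0.3), 100.0, "ode",
        ("x1' = x2", "x2' = -0.04*x1 - 0.016*x2 + 0.01"),
    ),
    ModelSpec(
        "IOSC", "Rising oscillator", BehaviourClass.PERIODIC, 2,
        {}, (0.1, 0.1), 100.0, "ode",
        ("x1' = x2", "x2' = -0.2*x1 + 0.08*x2 + 0.01"),
    ),
    ModelSpec(
        "QPS_1", "Quasi-periodic 1", BehaviourClass.QUASI_PERIODIC, 1,
        {"omega1": math.pi, "A1": 1.0, "A2": 1.0}, (2.0 * math.pi,), 1000.0, "explicit",
        ("x = cos(omega1*t/50 + x0) + cos(t/50 + x0)",),
    ),
    ModelSpec(
        "QPS_2", "Quasi-periodic 2", BehaviourClass.QUASI_PERIODIC, 1,
        {"omega1": _GOLDEN, "A1": 1.0, "A2": 1.0}, (2.0 * math.pi,), 1000.0, "explicit",
        ("x = sin(omega1*t/15 + x0) + sin(t/15 + x0)",),
    ),
    ModelSpec(
        "QPS_3", "Quasi-periodic 3", BehaviourClass.QUASI_PERIODIC, 1,
        {"omega1": math.e, "A1": 1.0, "A2": 1.0}, (2.0 * math.pi,), 1000.0, "explicit",
        ("x = sin(omega1*t/15 + x0) + cos(t/15 + x0)",),
    ),
    ModelSpec(
        "DS_1", "Damped system 1", BehaviourClass.NON_PERIODIC, 3,
        {}, (1.8, 2.3, 3.0), 100.0, "ode",
        ("x1' = -0.01*x1 + 0.01*x2",
         "x2' = -0.001*x1 - 0.01*x2",
         "x3' = 0.05*x1 - 0.03*x3"),
    ),
    ModelSpec(
        "DS_2", "Damped system 2", BehaviourClass.NON_PERIODIC, 3,
        {}, (3.0, -1.0, 2.0), 100.0, "ode",
        ("x1' = -0.05*x1 + 0.01*x2",
         "x2' = -0.001*x1 - 0.01*x2",
         "x3' = 0.05*x1 - 0.08*x3"),
    ),
)


def registry() -> list[ModelSpec]:
    """Return all 15 model specs, ordered by symbol."""
    return sorted(_SPECS, key=lambda m: m.symbol)


_BY_SYMBOL = {m.symbol: m for m in _SPECS}


def get_model(symbol: str) -> ModelSpec:
    try:
        return _BY_SYMBOL[symbol]
    except KeyError:
        raise KeyError(f"unknown model symbol {symbol!r}; known: {sorted(_BY_SYMBOL)}") from None


def _rhs_cha_1(p: Mapping[str, float]) -> Callable:
    b, A, Om = p["b"], p["A"], p["Omega"]

    def f(t, x):
        return np.array([x[1], -x[0] ** 3 - b * x[1] + A * math.sin(Om * t)])

    return f


def _rhs_cha_2(p):
    s, be, r = p["sigma"], p["beta"], p["rho"]

    def f(t, x):
        return np.array([
            -s * x[0] + s * x[1],
            r * x[0] - x[1] - x[0] * x[2],
            -be * x[2] + x[0] * x[1],
        ])

    return f


def _rhs_cha_3(p):
    a, b, c = p["a"], p["b"], p["c"]

    def f(t, x):
        return np.array([-x[1] - x[2], x[0] + a * x[1], b + x[2] * (x[0] - c)])

    return f


def _rhs_cha_4(p):
    a = p["a"]

    def f(t, x):
        return np.array([
            -a * x[0] - 4 * x[1] - 4 * x[2] - x[1] ** 2,
            -4 * x[0] - a * x[1] - 4 * x[2] - x[2] ** 2,
            -4 * x[0] - 4 * x[1] - a * x[2] - x[0] ** 2,
        ])

    return f


def _rhs_cha_5(p):
    k, lam = p["k"], p["lam"]

    def f(t, x):
        return np.array([-k * x[0] + lam * x[1] - x[1] * x[2], x[0], -x[2] + x[1] ** 2])

    return f


def _rhs_linear(A: np.ndarray, c: np.ndarray) -> Callable:
    A = np.asarray(A, dtype=float)
    c = np.asarray(c, dtype=float)

    def f(t, x):
        return A @ np.asarray(x, dtype=float) + c

    return f


# Coefficient matrices of the linear (periodic / non-periodic) models, straight
# from their state equations; the constant 0.01 forcing enters through c.
_LINEAR_SYSTEMS: dict[str, tuple[list[list[float]], list[float]]] = {
    "OSC_1": ([[0.0, 0.5], [-0.5, 0.0]], [0.0, 0.0]),
    "OSC_2": ([[0.0, 0.5], [-0.5, 0.0]], [0.0, 0.0]),
    "DOSC_1": ([[0.0, 1.0], [-0.2, -0.08]], [0.0, 0.01]),
    "DOSC_2": ([[0.0, 1.0], [-0.04, -0.016]], [0.0, 0.01]),
    "IOSC": ([[0.0, 1.0], [-0.2, 0.08]], [0.0, 0.01]),
    "DS_1": ([[-0.01, 0.01, 0.0], [-0.001, -0.01, 0.0], [0.05, 0.0, -0.03]], [0.0, 0.0, 0.0]),
    "DS_2": ([[-0.05, 0.01, 0.0], [-0.001, -0.01, 0.0], [0.05, 0.0, -0.08]], [0.0, 0.0, 0.0]),
}


def linear_system(symbol: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, c) with x' = A·x + c for a linear-model symbol."""
    A, c = _LINEAR_SYSTEMS[symbol]
    return np.asarray(A, dtype=float), np.asarray(c, dtype=float)


_RHS_BUILDERS: dict[str, Callable] = {
    "CHA_1": _rhs_cha_1,
    "CHA_2": _rhs_cha_2,
    "CHA_3": _rhs_cha_3,
    "CHA_4": _rhs_cha_4,
    "CHA_5": _rhs_cha_5,
}

_RHS_CACHE: dict[str, Callable] = {}


def _rhs_fn(model: ModelSpec) -> Callable:
    fn = _RHS_CACHE.get(model.symbol)
    if fn is None:
        if model.symbol in _RHS_BUILDERS:
            fn = _RHS_BUILDERS[model.symbol](model.params)
        else:
            fn = _rhs_linear(*linear_system(model.symbol))
        _RHS_CACHE[model.symbol] = fn
    return fn


def rhs(model: ModelSpec, t: float, x: Sequence[float]) -> np.ndarray:
    """Evaluate the state derivative x'(t, x) of an ODE-form model.

    Pure function of (t, x); t matters only for the driven Ueda oscillator
    (CHA_1), whose forcing is A·sin(Ω·t).
    """
    if model.form != "ode":
        raise ValueError(f"{model.symbol} is an explicit signal, not an ODE")
    x = np.asarray(x, dtype=float)
    if x.shape != (model.dim,):
        raise ValueError(f"{model.symbol}: state has shape {x.shape}, expected ({model.dim},)")
    return _rhs_fn(model)(t, x)


def explicit_value(model: ModelSpec, t, phase: float):
    """Evaluate an explicit quasi-periodic signal at time(s) ``t`` with given phase.

    Each signal is a sum of two unit-amplitude tones with irrational
    frequency ratio, so |value| <= 2 for every t and phase.  ``t`` may be a
    scalar or an array.
    """
    if model.form != "explicit":
        raise ValueError(f"{model.symbol} is ODE-form; use rhs/integrate")
    t = np.asarray(t, dtype=float)
    w1 = model.params["omega1"]
    if model.symbol == "QPS_1":
        return np.cos(w1 * t / 50.0 + phase) + np.cos(t / 50.0 + phase)
    if model.symbol == "QPS_2":
        return np.sin(w1 * t / 15.0 + phase) + np.sin(t / 15.0 + phase)
    if model.symbol == "QPS_3":
        return np.sin(w1 * t / 15.0 + phase) + np.cos(t / 15.0 + phase)
    raise ValueError(f"unknown explicit model {model.symbol!r}")


def registry_to_yaml() -> str:
    """Serialize the registry to a human-readable YAML document.

    One block per model (symbol, class, dim, params, x0, t_max, equations),
    so documentation and code cannot drift apart.
    """
    blocks = []
    for m in registry():
        blocks.append({
            "symbol": m.symbol,
            "name": m.name,
            "class": m.behaviour_class.value,
            "dim": m.dim,
            "params": {k: float(v) for k, v in m.params.items()},
            "x0": [float(v) for v in m.x0],
            "t_max": float(m.t_max),
            "form": m.form,
            "equations": list(m.equations),
        })
    return yaml.safe_dump(blocks, sort_keys=False, allow_unicode=True)
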