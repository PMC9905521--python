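"""Derivative-based phase-portrait embedding for univariate signals.

A scalar signal x(t) sampled at interval dt is lifted into a pseudo
state space with axes (x, x', x''), the derivatives approximated by
second-order central differences on interior points.  For quasi-periodic
two-tone signals the resulting portrait winds on a torus; for a harmonic
oscillation it is a closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EmbeddedPortrait", "derivative_embed", "save_portrait_figure"]


@dataclass(frozen=True)
class EmbeddedPortrait:
    """(s−2)×3 point cloud: columns (signal, dx/dt approx, d²x/dt² approx)."""

    points: np.ndarray
    dt: float

    @property
    def signal(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def first_derivative(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def second_derivative(self) -> np.ndarray:
        return self.points[:, 2]


def derivative_embed(signal, dt: float) -> EmbeddedPortrait:
    """Embed a signal as (x, x', x'') using central differences.

    x'_i  = (x_{i+1} − x_{i−1}) / (2·dt)
    x''_i = (x_{i+1} − 2·x_i + x_{i−1}) / dt²

    computed on interior points only, so a length-n input yields n−2 portrait
    points.  Both stencils are second-order accurate (error O(dt²)).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"signal must be 1-D, got shape {x.shape}")
    if x.size < 3:
        raise ValueError("signal must contain at least 3 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    d1 = (x[2:] - x[:-2]) / (2.0 * dt)
    d2 = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt**2
    points = np.column_stack([x[1:-1], d1, d2])
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite values in embedded portrait")
    return EmbeddedPortrait(points, float(dt))


def save_portrait_figure(portrait: EmbeddedPortrait, path, title: str | None = None) -> None:
    """Write a documentation figure: 2-D projections plus a 3-D scatter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(10, 8))
    p = portrait.points
    pairs = [((0, 1), "x vs x'"), ((0, 2), "x vs x''"), ((1, 2), "x' vs x''")]
    for k, ((i, j), label) in enumerate(pairs, start=1):
        ax = fig.add_subplot(2, 2, k)
        ax.plot(p[:, i], p[:, j], lw=0.4)
        ax.set_title(label)
    ax3 = fig.add_subplot(2, 2, 4, projection="3d")
    ax3.plot(p[:, 0], p[:, 1], p[:, 2], lw=0.3)
    ax3.set_title("(x, x', x'')")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
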