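"""Diffusive homeostasis via a nitric-oxide-like messenger.

Each spike produces messenger substance which diffuses over the group's
spatial grid and decays; the local concentration steers the firing threshold
toward a set point.  This is a minimal discrete rendition on the group's own
grid — production, a zero-flux finite-difference Laplacian, exponential
decay — not a re-implementation of a detailed reaction–diffusion model:

    n_i <- (1 - decay) * n_i + alpha * spike_i + D * laplacian(n)_i
    threshold_i <- threshold_i + eta_nox * (n_i - nox_target)

With ``decay=0`` and no spiking the total amount of messenger is conserved
exactly (the zero-flux Laplacian sums to zero).
"""
from __future__ import annotations

import numpy as np

from ..core import Behaviour, NetworkError, SpatialLayout


def grid_laplacian(values: np.ndarray, layout: SpatialLayout) -> np.ndarray:
    """Finite-difference Laplacian on the layout grid with zero-flux boundaries.

    Boundary cells use replicated edge values, which makes the operator
    mass-conserving: the entries of the returned vector sum to zero.
    """
    grid = values.reshape(layout.depth, layout.height, layout.width)
    lap = np.zeros_like(grid)
    for ax in range(3):
        if grid.shape[ax] > 1:
            pad = [(1, 1) if a == ax else (0, 0) for a in range(3)]
            p = np.pad(grid, pad, mode="edge")
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, -2)
            hi[ax] = slice(2, None)
            lap += p[tuple(lo)] + p[tuple(hi)] - 2.0 * grid
    return lap.reshape(values.shape)


class NOXHomeostasis(Behaviour):
    """Diffusion-based homeostatic threshold modulation.

    Parameters
    ----------
    alpha : float, default 0.1
        Messenger produced per spike.
    diffusion : float, default 0.1
        Diffusion coefficient D of the grid Laplacian (stable for D < 1/(2k)
        with k grid dimensions).
    decay : float in [0, 1], default 0.01
        Fraction of messenger lost per step.
    eta_nox : float, default 0.001
        Threshold adaptation rate.
    nox_target : float, default 1.0
        Concentration set point.
    """

    reads = frozenset({"spike", "threshold"})
    writes = frozenset({"threshold", "nox"})

    def set_variables(self, neurons):
        if neurons.layout is None:
            raise NetworkError(
                "NOXHomeostasis requires a spatial layout on the neuron group")
        self.alpha = float(self.get_init_attr("alpha", 0.1, diversify=False))
        self.diffusion = float(self.get_init_attr("diffusion", 0.1, diversify=False))
        self.decay = float(self.get_init_attr("decay", 0.01, diversify=False))
        self.eta = float(self.get_init_attr("eta_nox", 0.001, diversify=False))
        self.target = float(self.get_init_attr("nox_target", 1.0, diversify=False))
        for name, value in (("alpha", self.alpha), ("diffusion", self.diffusion),
                            ("eta_nox", self.eta)):
            if value < 0:
                raise NetworkError(f"{name} must be >= 0")
        if not 0.0 <= self.decay <= 1.0:
            raise NetworkError("decay must lie in [0, 1]")
        neurons.new_state_vector("nox", 0.0)
        if "threshold" not in neurons.state:
            neurons.new_state_vector("threshold", 0.5)

    def new_iteration(self, neurons):
        n = neurons.nox
        lap = grid_laplacian(n, neurons.layout)
        n = (1.0 - self.decay) * n \
            + self.alpha * np.asarray(neurons.spike, dtype=float) \
            + self.diffusion * lap
        neurons.nox = n
        neurons.threshold = neurons.threshold + self.eta * (n - self.target)
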