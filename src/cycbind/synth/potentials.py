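"""Analytic toy potentials standing in for the unknown true PMF of a
molecular system.

Each potential exposes ``energy`` and ``gradient`` (both vectorized over
numpy arrays) and a closed ``domain``. Energies are kcal/mol; the coordinate
is angstrom for distance-like variables and degrees for angular ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np


class Potential:
    """Base class: finite energy on a closed domain."""

    kind: str = "abstract"
    domain: Tuple[float, float] = (0.0, 1.0)

    def energy(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def in_domain(self, x) -> np.ndarray:
        lo, hi = self.domain
        x = np.asarray(x)
        return (x >= lo) & (x <= hi)


@dataclass
class HarmonicPotential(Potential):
    """U(x) = (kappa/2) (x - center)^2."""

    kappa: float = 1.0
    center: float = 0.0
    domain: Tuple[float, float] = (-10.0, 10.0)
    kind: str = "harmonic"

    def energy(self, x):
        return 0.5 * self.kappa * (np.asarray(x, dtype=float) - self.center) ** 2

    def gradient(self, x):
        return self.kappa * (np.asarray(x, dtype=float) - self.center)


@dataclass
class FlatPotential(Potential):
    """U(x) = 0 on the domain (uniform Boltzmann weight)."""

    domain: Tuple[float, float] = (0.0, 1.0)
    kind: str = "harmonic"  # degenerate harmonic with kappa = 0

    def energy(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))

    def gradient(self, x):
        return np.zeros_like(np.asarray(x, dtype=float))


@dataclass
class DoubleWellPotential(Potential):
    """Quartic double well.

    U(x) = barrier * ((x - center)^2 - half_sep^2)^2 / half_sep^4

    Minima at center +/- half_sep with U = 0; barrier height ``barrier``
    kcal/mol at x = center.
    """

    barrier: float = 3.0
    center: float = 0.0
    half_sep: float = 1.0
    domain: Tuple[float, float] = (-3.0, 3.0)
    kind: str = "double-well"

    def energy(self, x):
        d2 = (np.asarray(x, dtype=float) - self.center) ** 2
        return self.barrier * (d2 - self.half_sep**2) ** 2 / self.half_sep**4

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        d = x - self.center
        return self.barrier * 4.0 * d * (d**2 - self.half_sep**2) / self.half_sep**4


@dataclass
class TabulatedPotential(Potential):
    """Potential defined by linear interpolation of a strictly increasing grid."""

    grid: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    values: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0]))
    kind: str = "tabulated"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("tabulated grid needs >= 2 points")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("tabulated grid must be strictly increasing")
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tabulated potential must be finite on its domain")
        self.domain = (float(self.grid[0]), float(self.grid[-1]))

    def energy(self, x):
        return np.interp(np.asarray(x, dtype=float), self.grid, self.values)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        slopes = np.diff(self.values) / np.diff(self.grid)
        idx = np.clip(np.searchsorted(self.grid, x, side="right") - 1, 0, slopes.size - 1)
        return slopes[idx]


@dataclass
class AngularHarmonicPotential(Potential):
    """Periodic harmonic on an angle in degrees.

    U = (kappa/2) * wrap(x - center)^2, with the difference wrapped into
    (-180, 180]; kappa in kcal mol^-1 deg^-2.
    """

    kappa: float = 0.1
    center: float = 0.0
    domain: Tuple[float, float] = (-180.0, 180.0)
    kind: str = "angular-harmonic"

    @staticmethod
    def _wrap(d):
        return (np.asarray(d, dtype=float) + 180.0) % 360.0 - 180.0

    def energy(self, x):
        return 0.5 * self.kappa * self._wrap(np.asarray(x, dtype=float) - self.center) ** 2

    def gradient(self, x):
        return self.kappa * self._wrap(np.asarray(x, dtype=float) - self.center)
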