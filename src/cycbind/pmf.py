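"""Potential-of-mean-force estimation from biased sampling.

Two estimators are provided: self-consistent WHAM for (replica-exchange)
umbrella sampling with harmonic window biases, and trapezoid integration of
per-bin mean gradients for adaptive-biasing-force streams. Gradient streams
are assumed already unbiased (no extended-system deconvolution step), which
is how the synthetic generator produces them.

Uncertainties follow the half-split rule: re-estimate on the first and
second halves of the data and take the maximum absolute deviation from the
full-data estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from cycbind.synth.sampling import ExchangeLog, WindowSample, WindowSpec
from cycbind.thermo import ThermoState


@dataclass
class PMFProfile:
    """Gridded potential of mean force w(xi) along one collective variable."""

    grid: np.ndarray
    w: np.ndarray
    reference: str = "min-zero"  # min-zero | endpoint-zero | raw

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.grid.shape != self.w.shape or self.grid.ndim != 1:
            raise ValueError("grid and w must be congruent 1-D arrays")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("PMF grid must be strictly increasing")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("PMF values must be finite")

    def min_zero(self) -> "PMFProfile":
        return PMFProfile(self.grid, self.w - self.w.min(), "min-zero")

    def endpoint_zero(self) -> "PMFProfile":
        return PMFProfile(self.grid, self.w - self.w[-1], "endpoint-zero")

    def value_at(self, x: float) -> float:
        if x < self.grid[0] - 1e-9 or x > self.grid[-1] + 1e-9:
            raise ValueError(f"{x} outside PMF support [{self.grid[0]}, {self.grid[-1]}]")
        return float(np.interp(x, self.grid, self.w))


@dataclass
class WhamSolution:
    pmf: PMFProfile
    window_free_energies: np.ndarray
    iterations: int
    converged: bool
    residual: float


def wham(
    samples: Sequence[WindowSample],
    grid: Sequence[float],
    thermo: ThermoState = ThermoState(),
    tolerance: float = 1e-7,
    max_iter: int = 100000,
) -> WhamSolution:
    """Weighted histogram analysis of harmonic umbrella windows.

    ``grid`` gives histogram bin edges. Samples are pooled per window
    (standard practice for replica-exchange umbrella sampling). Iteration
    stops when the maximum change in window free energies falls below
    ``tolerance``; the first window's free energy is pinned to zero to fix
    the gauge. Bins with zero total count are dropped from the PMF support;
    if the visited bins are not contiguous the estimate is refused, naming
    the gap.
    """
    edges = np.asarray(grid, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("grid must be strictly increasing bin edges")
    if len(samples) == 0:
        raise ValueError("no window samples given")
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    beta = thermo.beta

    counts = np.array([np.histogram(s.values, bins=edges)[0] for s in samples])
    n_per_window = counts.sum(axis=1)
    if np.any(n_per_window == 0):
        empty = np.nonzero(n_per_window == 0)[0].tolist()
        raise ValueError(f"windows {empty} contributed no samples inside the grid")
    pooled = counts.sum(axis=0)
    visited = pooled > 0
    vis_idx = np.nonzero(visited)[0]
    gaps = np.nonzero(np.diff(vis_idx) > 1)[0]
    if gaps.size:
        g = vis_idx[gaps[0]]
        raise ValueError(
            "histogram support is disconnected: no samples between bin centers "
            f"{centers[g]:.4g} and {centers[vis_idx[gaps[0] + 1]]:.4g}; "
            "check window overlap"
        )

    c_vis = centers[visited]
    w_vis = widths[visited]
    m_vis = pooled[visited].astype(float)
    bias = np.array([s.window.bias_energy(c_vis) for s in samples])
    log_c = -beta * bias  # (n_windows, n_bins)

    f = np.zeros(len(samples))
    converged = False
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # p_m proportional to pooled counts reweighted by current f
        log_denom = np.logaddexp.reduce(
            np.log(n_per_window)[:, None] + beta * f[:, None] + log_c, axis=0
        )
        log_p = np.log(m_vis) - log_denom
        log_p -= np.logaddexp.reduce(log_p)  # normalize bin probabilities
        f_new = -thermo.kT * np.logaddexp.reduce(log_c + log_p[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual <= tolerance:
            converged = True
            break

    log_denom = np.logaddexp.reduce(
        np.log(n_per_window)[:, None] + beta * f[:, None] + log_c, axis=0
    )
    log_p = np.log(m_vis) - log_denom
    log_p -= np.logaddexp.reduce(log_p)
    w = -thermo.kT * (log_p - np.log(w_vis))  # density, not bin mass
    profile = PMFProfile(c_vis, w - w.min(), "min-zero")
    return WhamSolution(pmf=profile, window_free_energies=f, iterations=it,
                        converged=converged, residual=residual)


def abf_pmf(
    gradient_samples: np.ndarray,
    grid: Sequence[float],
    thermo: ThermoState = ThermoState(),
    min_count: int = 1,
) -> PMFProfile:
    """Integrate per-bin mean gradients into a PMF (cumulative trapezoid).

    ``gradient_samples`` has one row of dU/dxi samples per bin of ``grid``
    (bin centers, strictly increasing). ``thermo`` is accepted for interface
    symmetry with :func:`wham`; the integration itself is temperature-free.
    """
    del thermo
    centers = np.asarray(grid, dtype=float)
    if centers.ndim != 1 or centers.size < 2:
        raise ValueError("grid must contain >= 2 bin centers")
    if not np.all(np.diff(centers) > 0):
        raise ValueError("grid must be strictly increasing (reversed input rejected)")
    rows = [np.asarray(r, dtype=float).ravel() for r in gradient_samples]
    if len(rows) != centers.size:
        raise ValueError("one row of gradient samples per bin required")
    short = [i for i, r in enumerate(rows) if r.size < min_count]
    if short:
        raise ValueError(f"bins with fewer than {min_count} gradient samples: {short}")
    means = np.array([r.mean() for r in rows])
    w = np.concatenate([[0.0], np.cumsum(0.5 * (means[1:] + means[:-1]) * np.diff(centers))])
    return PMFProfile(centers, w - w.min(), "min-zero")


def overlap_matrix(samples: Sequence[WindowSample], grid: Sequence[float]) -> np.ndarray:
    """Pairwise histogram overlap: sum_bins min(p_i, p_j), in [0, 1]."""
    if len(samples) < 2:
        raise ValueError("need >= 2 windows")
    edges = np.asarray(grid, dtype=float)
    hists = []
    for s in samples:
        h, _ = np.histogram(s.values, bins=edges)
        tot = h.sum()
        if tot == 0:
            raise ValueError(f"window {s.window.index} has no samples inside the grid")
        hists.append(h / tot)
    hists = np.asarray(hists)
    n = hists.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = np.minimum(hists[i], hists[j]).sum()
    return out


@dataclass
class UncertaintyEstimate:
    value: float
    half1: float
    half2: float

    @property
    def uncertainty(self) -> float:
        return max(abs(self.half1 - self.value), abs(self.half2 - self.value))


def half_split_uncertainty(
    estimator: Callable[[Sequence], float],
    data: Sequence,
) -> UncertaintyEstimate:
    """Half-split uncertainty: max |estimate(half) - estimate(full)|.

    The first half receives floor(n/2) samples. Estimator failures on a
    half are re-raised with context.
    """
    n = len(data)
    if n < 2:
        raise ValueError("need >= 2 samples to split")
    k = n // 2
    value = float(estimator(data))
    try:
        half1 = float(estimator(data[:k]))
        half2 = float(estimator(data[k:]))
    except Exception as exc:
        raise RuntimeError(f"estimator failed on a data half: {exc}") from exc
    return UncertaintyEstimate(value=value, half1=half1, half2=half2)


def exchange_acceptance_report(log: ExchangeLog) -> Dict[Tuple[int, int], Dict[str, float]]:
    """Per-adjacent-pair exchange acceptance rates from a REUS exchange log."""
    if not log.pairs:
        raise ValueError("exchange log is empty")
    out: Dict[Tuple[int, int], Dict[str, float]] = {}
    for pair, ok in zip(log.pairs, log.accepted):
        entry = out.setdefault(tuple(pair), {"attempted": 0, "accepted": 0})
        entry["attempted"] += 1
        entry["accepted"] += int(ok)
    for entry in out.values():
        entry["rate"] = entry["accepted"] / entry["attempted"]
    return out


def write_pmf(profile: PMFProfile, path) -> None:
    lines = [f"# reference={profile.reference}", "# xi\tw_kcal_per_mol"]
    lines += [f"{x:.10g}\t{w:.10g}" for x, w in zip(profile.grid, profile.w)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pmf(path) -> PMFProfile:
    reference = "raw"
    xs, ws = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "reference=" in line:
                reference = line.split("reference=")[1].strip()
            continue
        if line.strip():
            a, b = line.split()[:2]
            xs.append(float(a))
            ws.append(float(b))
    return PMFProfile(np.asarray(xs), np.asarray(ws), reference)
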