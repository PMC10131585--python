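"""Boltzmann samplers, umbrella-window grids, replica exchange, and
ABF-style gradient streams.

The sampler is a Metropolis random walk (overdamped Langevin optional)
whose only job is to realize the stationary distribution
exp(-beta [U(x) + bias(x)]) on the potential's domain; no attempt is made
to emulate molecular dynamics itself. All routines are deterministic given
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from cycbind.synth.potentials import Potential
from cycbind.thermo import ThermoState


@dataclass(frozen=True)
class WindowSpec:
    """One umbrella window: harmonic bias u(x) = (k/2)(x - center)^2.

    ``force_constant`` is the full harmonic constant in kcal mol^-1 A^-2
    (some packages write the bias without the 1/2; this one keeps it).
    """

    center: float
    force_constant: float = 10.0
    index: int = 0

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")

    def bias_energy(self, x):
        return 0.5 * self.force_constant * (np.asarray(x, dtype=float) - self.center) ** 2


@dataclass(frozen=True)
class SamplerConfig:
    scheme: str = "metropolis"
    n_steps: int = 20000
    step_size: float = 0.5
    seed: int = 0
    record_interval: int = 10
    n_walkers: int = 32
    burn_in_fraction: float = 0.1
    tune: bool = True

    def __post_init__(self):
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")
        if self.scheme not in ("metropolis", "overdamped-langevin"):
            raise ValueError(f"unknown sampler scheme {self.scheme!r}")
        if self.record_interval <= 0 or self.n_walkers <= 0:
            raise ValueError("record_interval and n_walkers must be > 0")


@dataclass
class WindowSample:
    """Biased coordinate samples from one umbrella window."""

    window: WindowSpec
    values: np.ndarray
    source_potential: Optional[Potential] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("WindowSample must be non-empty")


@dataclass(frozen=True)
class REUSConfig:
    windows: Tuple[WindowSpec, ...]
    exchange_interval: int = 250
    alternation: str = "even-first"
    seed: int = 0

    def __post_init__(self):
        centers = [w.center for w in self.windows]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("window centers must be strictly increasing")
        if self.exchange_interval <= 0:
            raise ValueError("exchange_interval must be > 0")
        if self.alternation not in ("even-first", "odd-first"):
            raise ValueError("alternation must be 'even-first' or 'odd-first'")


@dataclass
class ExchangeLog:
    """Record of replica-exchange attempts between adjacent windows."""

    pairs: List[Tuple[int, int]] = field(default_factory=list)
    steps: List[int] = field(default_factory=list)
    accepted: List[bool] = field(default_factory=list)

    def record(self, step: int, pair: Tuple[int, int], ok: bool) -> None:
        self.steps.append(step)
        self.pairs.append(pair)
        self.accepted.append(bool(ok))


def make_window_grid(lo: float, hi: float, spacing: float, force_constant: float) -> List[WindowSpec]:
    """Regular umbrella-window grid with centers lo, lo+spacing, ..., hi.

    The reference stage-3 grid is ``make_window_grid(16.5, 26.0, 0.5, 10.0)``
    which gives 20 windows.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    n_intervals = (hi - lo) / spacing
    if abs(n_intervals - round(n_intervals)) > 1e-9:
        raise ValueError(
            f"range not commensurate with spacing: lo={lo}, hi={hi}, "
            f"spacing={spacing} ((hi-lo)/spacing = {n_intervals})"
        )
    n = int(round(n_intervals)) + 1
    centers = lo + spacing * np.arange(n)
    return [WindowSpec(center=float(c), force_constant=force_constant, index=i) for i, c in enumerate(centers)]


def _total_energy(potential: Potential, window: Optional[WindowSpec], x):
    e = potential.energy(x)
    if window is not None and window.force_constant > 0:
        e = e + window.bias_energy(x)
    return e


def _init_positions(potential: Potential, window: Optional[WindowSpec], n: int, rng) -> np.ndarray:
    lo, hi = potential.domain
    if window is not None and window.force_constant > 0:
        x0 = np.clip(window.center, lo, hi)
        x = x0 + 0.01 * (hi - lo) * rng.standard_normal(n)
        return np.clip(x, lo, hi)
    return rng.uniform(lo, hi, size=n)


def _metropolis_chain(
    potential: Potential,
    window: Optional[WindowSpec],
    config: SamplerConfig,
    thermo: ThermoState,
) -> np.ndarray:
    """Vectorized Metropolis walk: n_walkers independent chains.

    Returns recorded samples with shape (n_recorded, n_walkers).
    """
    rng = np.random.default_rng(config.seed)
    beta = thermo.beta
    lo, hi = potential.domain
    x = _init_positions(potential, window, config.n_walkers, rng)
    e = _total_energy(potential, window, x)
    step = float(config.step_size)

    n_burn = max(1, int(config.burn_in_fraction * config.n_steps))
    langevin = config.scheme == "overdamped-langevin"
    records = []
    acc_win = 0
    att_win = 0
    burn_accepted = 0
    for t in range(config.n_steps):
        if langevin:
            # Euler-Maruyama proposal + Metropolis correction (MALA)
            grad = potential.gradient(x)
            if window is not None and window.force_constant > 0:
                grad = grad + window.force_constant * (x - window.center)
            drift = -0.5 * step**2 * beta * grad
            prop = x + drift + step * rng.standard_normal(x.shape)
            e_prop = _total_energy(potential, window, prop)
            grad_p = potential.gradient(prop)
            if window is not None and window.force_constant > 0:
                grad_p = grad_p + window.force_constant * (prop - window.center)
            drift_p = -0.5 * step**2 * beta * grad_p
            log_q_fwd = -((prop - x - drift) ** 2) / (2 * step**2)
            log_q_rev = -((x - prop - drift_p) ** 2) / (2 * step**2)
            log_alpha = -beta * (e_prop - e) + log_q_rev - log_q_fwd
        else:
            prop = x + step * rng.uniform(-1.0, 1.0, size=x.shape)
            e_prop = _total_energy(potential, window, prop)
            log_alpha = -beta * (e_prop - e)
        inside = (prop >= lo) & (prop <= hi)
        accept = inside & (np.log(rng.uniform(size=x.shape)) < log_alpha)
        x = np.where(accept, prop, x)
        e = np.where(accept, e_prop, e)
        n_acc = int(accept.sum())
        acc_win += n_acc
        att_win += accept.size
        if t < n_burn:
            burn_accepted += n_acc
            if config.tune and att_win >= 50 * config.n_walkers:
                rate = acc_win / att_win
                if rate > 0.5:
                    step *= 1.2
                elif rate < 0.3:
                    step *= 0.8
                acc_win = att_win = 0
        else:
            if (t - n_burn) % config.record_interval == 0:
                records.append(x.copy())
    if burn_accepted == 0:
        raise RuntimeError(
            "sampler accepted no moves during burn-in; check the potential "
            "domain, bias center, and step size"
        )
    if not records:
        raise RuntimeError("no samples recorded; increase n_steps")
    return np.asarray(records)


def sample_biased(
    potential: Potential,
    window: WindowSpec,
    config: SamplerConfig,
    thermo: ThermoState = ThermoState(),
) -> WindowSample:
    """Sample exp(-beta [U(x) + (k/2)(x-center)^2]) on the potential's domain."""
    rec = _metropolis_chain(potential, window, config, thermo)
    return WindowSample(window=window, values=rec.ravel(), source_potential=potential)


def sample_unbiased(
    potential: Potential,
    config: SamplerConfig,
    thermo: ThermoState = ThermoState(),
) -> np.ndarray:
    """Sample the bare Boltzmann distribution exp(-beta U(x))."""
    rec = _metropolis_chain(potential, None, config, thermo)
    return rec.ravel()


def run_reus(
    potential: Potential,
    config: REUSConfig,
    sampler: SamplerConfig,
    thermo: ThermoState = ThermoState(),
) -> Tuple[List[WindowSample], ExchangeLog]:
    """Replica-exchange umbrella sampling on a toy potential.

    One Metropolis chain per window; every ``exchange_interval`` production
    steps, adjacent windows (w, w+1) attempt configuration swaps, with w
    alternating between even and odd. A swap is accepted with probability
    min(1, exp(-beta * Delta)) where
    Delta = [u_i(x_j) + u_j(x_i)] - [u_i(x_i) + u_j(x_j)]
    and u_w is window w's bias (the unbiased potential energy cancels).
    """
    windows = list(config.windows)
    if len(windows) < 2:
        raise ValueError("replica exchange needs >= 2 windows")
    rng = np.random.default_rng(config.seed)
    beta = thermo.beta
    lo, hi = potential.domain

    # one walker per window
    x = np.array([
        float(np.clip(w.center, lo, hi)) + 0.01 * (hi - lo) * rng.standard_normal()
        for w in windows
    ])
    x = np.clip(x, lo, hi)
    centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constant for w in windows])

    def energies(pos):
        return potential.energy(pos) + 0.5 * ks * (pos - centers) ** 2

    e = energies(x)
    step = np.full(len(windows), float(sampler.step_size))

    n_burn = max(1, int(sampler.burn_in_fraction * sampler.n_steps))
    acc = np.zeros(len(windows))
    att = 0
    log = ExchangeLog()
    records = [[] for _ in windows]
    parity = 0 if config.alternation == "even-first" else 1
    exchange_count = 0

    for t in range(sampler.n_steps):
        prop = x + step * rng.uniform(-1.0, 1.0, size=x.shape)
        e_prop = energies(prop)
        inside = (prop >= lo) & (prop <= hi)
        accept = inside & (np.log(rng.uniform(size=x.shape)) < -beta * (e_prop - e))
        x = np.where(accept, prop, x)
        e = np.where(accept, e_prop, e)
        if t < n_burn:
            acc += accept
            att += 1
            if sampler.tune and att >= 50:
                rate = acc / att
                step = np.where(rate > 0.5, step * 1.2, np.where(rate < 0.3, step * 0.8, step))
                acc[:] = 0.0
                att = 0
            continue
        tp = t - n_burn
        if tp % sampler.record_interval == 0:
            for i, xi in enumerate(x):
                records[i].append(xi)
        if (tp + 1) % config.exchange_interval == 0:
            start = (parity + exchange_count) % 2
            for i in range(start, len(windows) - 1, 2):
                j = i + 1
                delta = (
                    0.5 * ks[i] * (x[j] - centers[i]) ** 2
                    + 0.5 * ks[j] * (x[i] - centers[j]) ** 2
                    - 0.5 * ks[i] * (x[i] - centers[i]) ** 2
                    - 0.5 * ks[j] * (x[j] - centers[j]) ** 2
                )
                ok = np.log(rng.uniform()) < -beta * delta
                log.record(t, (i, j), ok)
                if ok:
                    x[i], x[j] = x[j], x[i]
                    e = energies(x)
            exchange_count += 1

    samples = [
        WindowSample(window=w, values=np.asarray(r), source_potential=potential)
        for w, r in zip(windows, records)
    ]
    return samples, log


def generate_abf_gradient_stream(
    potential: Potential,
    grid: Sequence[float],
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Idealized per-bin free-energy gradient samples.

    Emulates the accumulated mean-force estimates an adaptive-biasing-force
    run would deposit: for each bin of ``grid`` (edges), draws ``n_samples``
    values dU/dx(bin center) + N(0, noise_sd). Returns
    (bin_centers, samples[n_bins, n_samples]).
    """
    edges = np.asarray(grid, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("grid must contain >= 2 bin edges")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("grid edges must be strictly increasing")
    lo, hi = potential.domain
    if edges[0] < lo - 1e-9 or edges[-1] > hi + 1e-9:
        raise ValueError("grid must lie within the potential domain")
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    centers = 0.5 * (edges[:-1] + edges[1:])
    true_grad = potential.gradient(centers)
    rng = np.random.default_rng(seed)
    noise = noise_sd * rng.standard_normal((centers.size, n_samples)) if noise_sd > 0 else 0.0
    samples = true_grad[:, None] + noise
    if noise_sd == 0:
        samples = np.broadcast_to(true_grad[:, None], (centers.size, n_samples)).copy()
    return centers, samples
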