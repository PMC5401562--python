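"""Stochastic simulation of trimeric-channel gating and trace rendering.

A channel built from N identical, independently gating monomeric pores is an
aggregated birth--death Markov chain on the occupancy levels m = 0..N
(number of open monomers), with transition rates

    up(m)   = (N - m) * k_open
    down(m) = m * k_close

The stationary occupancy is Binomial(N, p) with p = k_open/(k_open+k_close).
Conductance levels are free parameters rather than forced multiples of the
single-pore conductance: measured multi-pore levels are sub-additive (for
the wild-type trimer 42.2, 100.6, 163.7 pS for one, two, three open pores).

`render_trace` turns a state path into a sampled current record emulating
the acquisition chain of an inside-out patch recording: 50 kHz sampling, a
0.5 kHz low-pass filter (Gaussian kernel, -3 dB at the cutoff), and additive
Gaussian baseline noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .ghk import DEFAULT_PERMEABILITY_SCALE, IonConditions, ghk_current, ghk_reversal

__all__ = [
    "GatingModel",
    "RecordingConfig",
    "StatePath",
    "Trace",
    "simulate_state_path",
    "render_trace",
    "ghk_current",
]


@dataclass(frozen=True)
class GatingModel:
    """Independent-monomer gating model for an N-mer channel.

    ``level_conductances[m]`` is the total conductance in pS with m monomers
    open; entry 0 must be 0 and entries must be non-decreasing.
    """

    k_open: float
    k_close: float
    level_conductances: tuple
    n_monomers: int = 3

    def __post_init__(self):
        if self.k_open < 0 or self.k_close < 0 or (self.k_open == 0 and self.k_close == 0):
            raise ValueError("rates must be non-negative and not both zero")
        g = tuple(float(x) for x in self.level_conductances)
        if len(g) != self.n_monomers + 1:
            raise ValueError(f"need {self.n_monomers + 1} conductance levels, got {len(g)}")
        if g[0] != 0.0:
            raise ValueError("closed-level conductance must be 0")
        if any(b < a for a, b in zip(g, g[1:])):
            raise ValueError("level conductances must be non-decreasing")
        object.__setattr__(self, "level_conductances", g)

    @property
    def p_open(self) -> float:
        """Per-monomer stationary open probability k_open/(k_open+k_close)."""
        return self.k_open / (self.k_open + self.k_close)

    def stationary_occupancy(self) -> np.ndarray:
        """Binomial(N, p_open) stationary distribution over levels 0..N."""
        from scipy.stats import binom

        return binom.pmf(np.arange(self.n_monomers + 1), self.n_monomers, self.p_open)


@dataclass(frozen=True)
class RecordingConfig:
    """Acquisition settings for rendering a trace."""

    duration: float
    holding_potential: float
    noise_sd: float = 0.0
    sampling_rate: float = 50_000.0
    filter_cutoff: float | None = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.filter_cutoff is not None and self.sampling_rate <= 2 * self.filter_cutoff:
            raise ValueError("sampling_rate must exceed twice the filter cutoff")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


@dataclass
class StatePath:
    """Realization of the aggregated gating chain: levels and dwell durations."""

    levels: np.ndarray
    durations: np.ndarray
    total_duration: float
    n_monomers: int

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be positive")
        if self.levels.min(initial=0) < 0 or self.levels.max(initial=0) > self.n_monomers:
            raise ValueError("levels outside [0, n_monomers]")
        if len(self.levels) > 1 and np.any(np.abs(np.diff(self.levels)) != 1):
            raise ValueError("consecutive levels must differ by exactly 1")
        if not np.isclose(self.durations.sum(), self.total_duration, rtol=1e-9, atol=1e-9):
            raise ValueError("durations must sum to total_duration")

    @property
    def n_transitions(self) -> int:
        return len(self.levels) - 1

    def time_fractions(self) -> np.ndarray:
        """Fraction of total time spent at each level 0..n_monomers."""
        out = np.bincount(self.levels, weights=self.durations, minlength=self.n_monomers + 1)
        return out / self.total_duration


@dataclass
class Trace:
    """Sampled current record with its acquisition metadata."""

    samples: np.ndarray
    dt: float
    holding_potential: float
    conditions: IonConditions | None = None
    seed: int | None = None
    filter_cutoff: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return len(self.samples) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


_CHUNK = 1 << 14


def simulate_state_path(
    model: GatingModel,
    duration: float,
    seed: int,
    start_level: int | None = None,
) -> StatePath:
    """Exact stochastic (Gillespie) simulation of the aggregated gating chain.

    Waiting times are drawn by inverse-CDF from pre-generated uniforms so a
    fixed seed reproduces the path exactly.  The initial level defaults to a
    draw from the stationary Binomial(N, p_open) distribution; the final
    dwell is truncated so durations sum exactly to ``duration``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = model.n_monomers
    ko, kc = model.k_open, model.k_close

    if start_level is None:
        m = int(rng.binomial(n, model.p_open))
    else:
        if not 0 <= start_level <= n:
            raise ValueError("start_level outside [0, n_monomers]")
        m = int(start_level)

    levels: list[int] = []
    durations: list[float] = []
    t = 0.0
    buf = rng.random((_CHUNK, 2))
    i = 0
    while t < duration:
        up = (n - m) * ko
        down = m * kc
        total = up + down
        if total == 0.0:  # absorbing level
            levels.append(m)
            durations.append(duration - t)
            t = duration
            break
        if i >= _CHUNK:
            buf = rng.random((_CHUNK, 2))
            i = 0
        u_wait, u_dir = buf[i]
        i += 1
        dwell = -np.log1p(-u_wait) / total  # inverse-CDF exponential
        if t + dwell >= duration:
            dwell = duration - t
            levels.append(m)
            durations.append(dwell)
            t = duration
            break
        levels.append(m)
        durations.append(dwell)
        t += dwell
        m = m + 1 if u_dir < up / total else m - 1

    return StatePath(
        levels=np.array(levels),
        durations=np.array(durations),
        total_duration=duration,
        n_monomers=n,
    )


def filter_sigma_samples(filter_cutoff: float, sampling_rate: float) -> float:
    """Gaussian-kernel sd (in samples) whose -3 dB point sits at the cutoff.

    |H(f)| = exp(-2 pi^2 sigma_t^2 f^2) = 1/sqrt(2) at f_c gives
    sigma_t = sqrt(ln 2) / (2 pi f_c) ~= 0.1325 / f_c.
    """
    sigma_t = np.sqrt(np.log(2.0)) / (2.0 * np.pi * filter_cutoff)
    return sigma_t * sampling_rate


def render_trace(
    path: StatePath,
    config: RecordingConfig,
    conditions: IonConditions,
    model: GatingModel,
) -> Trace:
    """Render a state path into a sampled, noisy, filtered current trace.

    The per-sample current at occupancy level m is

        I_m = level_conductances[m] * (V - E_rev) / 1000    [pA from pS * mV]

    with E_rev the GHK reversal potential of the ionic conditions.  Gaussian
    noise of sd ``noise_sd`` is added per sample, then the trace is low-pass
    filtered (Gaussian kernel, -3 dB at ``filter_cutoff``) unless the cutoff
    is None.  Noise uses the same seed stream convention as the path: the
    config seed alone determines the noise.
    """
    if path.total_duration < config.duration - 1e-12:
        raise ValueError("state path shorter than the requested recording duration")
    e_rev = ghk_reversal(conditions)
    level_currents = (
        np.asarray(model.level_conductances) * (config.holding_potential - e_rev) / 1000.0
    )

    edges = np.concatenate([[0.0], np.cumsum(path.durations)])
    sample_times = (np.arange(config.n_samples) + 0.5) / config.sampling_rate
    idx = np.searchsorted(edges, sample_times, side="right") - 1
    idx = np.clip(idx, 0, len(path.levels) - 1)
    samples = level_currents[path.levels[idx]]

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.shape)
    if config.filter_cutoff is not None:
        sigma = filter_sigma_samples(config.filter_cutoff, config.sampling_rate)
        samples = gaussian_filter1d(samples, sigma, mode="nearest")

    return Trace(
        samples=samples,
        dt=config.dt,
        holding_potential=config.holding_potential,
        conditions=conditions,
        seed=config.seed,
        filter_cutoff=config.filter_cutoff,
        metadata={"e_rev_mV": e_rev, "level_currents_pA": level_currents.tolist()},
    )
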