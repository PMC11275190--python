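"""Synthetic voltage and current traces with condition-calibrated statistics.

The generator emulates the statistical structure of proteinoid microsphere
recordings under graded chloroform exposure:

* spike amplitudes follow a three-parameter (shifted) gamma law whose
  post-clipping mean and SD match the per-condition targets;
* interspike intervals follow a normal law truncated to the per-condition
  observed range, with the truncated mean matched exactly and the truncated
  SD matched as closely as the family permits;
* spikes are rendered as biexponential pulses riding on a slow sinusoidal
  baseline drift plus white noise;
* chronoamperometric current traces carry a condition-dependent baseline with
  transient conductivity spikes that relax exponentially on subsecond
  timescales.

All randomness flows through a single seeded :class:`numpy.random.Generator`
per call, so identical (spec, seed) inputs give bit-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import erfcx, gammainc

from .conditions import CURRENT_BASELINE_UA, ConditionSpec
from .errors import InfeasibleMomentsError
from .io import Trace

__all__ = [
    "SpikeEventList",
    "gamma_from_moments",
    "fit_truncated_normal",
    "truncated_normal_moments",
    "sample_amplitudes",
    "sample_isis",
    "render_trace",
    "generate_condition_trace",
    "generate_current_trace",
]


@dataclass
class SpikeEventList:
    """Spike peak times (s, strictly increasing) and amplitudes (mV)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def isis(self) -> np.ndarray:
        """Successive differences of peak times (s)."""
        return np.diff(self.times)


# ---------------------------------------------------------------------------
# amplitude law: shifted gamma
# ---------------------------------------------------------------------------

def gamma_from_moments(mean: float, sd: float, skew: float):
    """Moment-match a shifted gamma to (mean, sd, skew); skew must be > 0.

    Solves shape = (2/skew)^2, scale = sd/sqrt(shape),
    shift = mean - shape*scale. Gamma skewness 2/sqrt(shape) is unbounded
    above, so any positive target is representable (unlike e.g. the
    skew-normal family, capped near 0.995).
    """
    if skew <= 0:
        raise ValueError("shifted-gamma orientation requires skew > 0")
    if sd <= 0:
        raise ValueError("sd must be strictly positive")
    shape = (2.0 / skew) ** 2
    scale = sd / math.sqrt(shape)
    shift = mean - shape * scale
    return shape, scale, shift


def _clipped_gamma_mean_sd(shape, scale, shift, lo, hi):
    """Exact mean/SD of a shifted gamma hard-clipped to [lo, hi].

    Uses closed-form partial moments via the regularized lower incomplete
    gamma function (robust for shape < 1, where the density is singular at
    the shift and quadrature fails).
    """
    zlo = max(lo - shift, 0.0) / scale
    zhi = max(hi - shift, 0.0) / scale
    dF = gammainc(shape, zhi) - gammainc(shape, zlo)
    dP1 = gammainc(shape + 1, zhi) - gammainc(shape + 1, zlo)
    dP2 = gammainc(shape + 2, zhi) - gammainc(shape + 2, zlo)
    Flo = gammainc(shape, zlo)
    Shi = 1.0 - gammainc(shape, zhi)
    k, th = shape, scale
    m1 = lo * Flo + hi * Shi + shift * dF + k * th * dP1
    m2 = (lo ** 2 * Flo + hi ** 2 * Shi + shift ** 2 * dF
          + 2 * shift * k * th * dP1 + k * (k + 1) * th * th * dP2)
    return m1, math.sqrt(max(m2 - m1 * m1, 0.0))


def _calibrated_gamma(spec: ConditionSpec):
    """Gamma parameters whose CLIPPED law matches the spec mean/SD.

    Hard clipping to [amp_min, amp_max] shifts the moments of the underlying
    gamma (SD drops by ~10% for the built-in conditions), so the underlying
    (mean, sd) are adjusted by least squares until the clipped moments land
    on target. The skew parameter is held at the spec value: a 3-parameter
    family cannot pin a fourth (post-clip) moment, and bounded support caps
    the attainable clipped skewness anyway.
    """
    tgt_m, tgt_s = spec.amp_mean, spec.amp_sd

    def resid(p):
        sh, sc, sf = gamma_from_moments(p[0], p[1], spec.amp_skew)
        m, s = _clipped_gamma_mean_sd(sh, sc, sf, spec.amp_min, spec.amp_max)
        return [(m - tgt_m) / tgt_m, (s - tgt_s) / tgt_s]

    sol = optimize.least_squares(resid, [tgt_m, tgt_s], diff_step=1e-5)
    return gamma_from_moments(sol.x[0], sol.x[1], spec.amp_skew)


def sample_amplitudes(spec: ConditionSpec, n: int, seed: int | None = None,
                      calibrate_clipping: bool = True) -> np.ndarray:
    """Draw ``n`` spike amplitudes (mV) for a condition.

    Positive target skewness uses the shifted gamma; ``amp_skew <= 0`` falls
    back to a normal truncated to [amp_min, amp_max] (the gamma orientation
    used here cannot represent left or zero skew). Draws are clipped to the
    condition's amplitude bounds. With ``calibrate_clipping`` the gamma is
    recalibrated so the clipped mean/SD match the targets; disabling it uses
    the plain unclipped moment match.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.amp_sd > (spec.amp_max - spec.amp_min) / 2:
        raise InfeasibleMomentsError(
            f"amplitude SD {spec.amp_sd} exceeds the Popoviciu bound "
            f"{(spec.amp_max - spec.amp_min) / 2} for the clipping range")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.amp_skew <= 0:
        mu, sigma = fit_truncated_normal(spec.amp_mean, spec.amp_sd,
                                         spec.amp_min, spec.amp_max)
        return _sample_truncnorm(rng, mu, sigma, spec.amp_min, spec.amp_max, n)
    if calibrate_clipping:
        shape, scale, shift = _calibrated_gamma(spec)
    else:
        shape, scale, shift = gamma_from_moments(spec.amp_mean, spec.amp_sd,
                                                 spec.amp_skew)
    x = shift + scale * rng.standard_gamma(shape, size=n)
    return np.clip(x, spec.amp_min, spec.amp_max)


# ---------------------------------------------------------------------------
# ISI law: truncated normal
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
_SQRT_2_PI = math.sqrt(2.0 / math.pi)


def truncated_normal_moments(mu: float, sigma: float,
                             lo: float, hi: float) -> tuple[float, float]:
    """Mean and SD of N(mu, sigma) truncated to [lo, hi].

    Numerically stable in the far tails (both bounds many sigma from mu) via
    the scaled complementary error function; plain Phi-ratio formulas
    underflow there.
    """
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    if b < 0:  # reflect so the analysis below always sees a <= b with b >= 0
        m, s = truncated_normal_moments(-mu, sigma, -hi, -lo)
        return -m, s
    if a > 0:
        d = math.exp((a * a - b * b) / 2.0)  # <= 1
        denom = erfcx(a / _SQRT2) - erfcx(b / _SQRT2) * d
        ra = _SQRT_2_PI / denom              # phi(a)/Z
        rb = ra * d                          # phi(b)/Z
    else:
        Z = stats.norm.cdf(b) - stats.norm.cdf(a)
        ra = stats.norm.pdf(a) / Z
        rb = stats.norm.pdf(b) / Z
    delta = ra - rb
    mean = mu + sigma * delta
    var = sigma * sigma * (1.0 + a * ra - b * rb - delta * delta)
    return mean, math.sqrt(max(var, 0.0))


def _mu_for_mean(sigma: float, target: float, lo: float, hi: float) -> float:
    """Location mu such that the [lo,hi]-truncated mean equals ``target``.

    The truncated mean is strictly increasing in mu and spans (lo, hi), so a
    bracketing root find always succeeds for interior targets.
    """
    if not (lo < target < hi):
        raise InfeasibleMomentsError(
            f"target mean {target} outside truncation range ({lo}, {hi})")

    def f(mu):
        return truncated_normal_moments(mu, sigma, lo, hi)[0] - target

    blo, bhi = lo - 8 * sigma, hi + 8 * sigma
    while f(blo) > 0:
        blo -= 8 * sigma
    while f(bhi) < 0:
        bhi += 8 * sigma
    return optimize.brentq(f, blo, bhi, xtol=1e-10 * (hi - lo), maxiter=200)


def fit_truncated_normal(mean: float, sd: float, lo: float, hi: float,
                         strict: bool = False,
                         rel_tol: float = 0.01) -> tuple[float, float]:
    """Solve for (mu, sigma) so the [lo,hi]-truncated moments hit (mean, sd).

    The truncated mean is matched exactly at every candidate sigma; the
    truncated SD is then a monotone function of sigma, solved by bisection.
    If the requested SD exceeds what the family can attain on the range
    (its supremum is below the Popoviciu bound (hi-lo)/2), the solver
    saturates at the maximising sigma and either raises
    :class:`InfeasibleMomentsError` (``strict``) or returns the best
    achievable fit. ``rel_tol`` is the SD tolerance separating "matched"
    from "infeasible".
    """
    if np.isinf(lo) and np.isinf(hi):
        return mean, sd  # no truncation: plain normal
    if sd <= 0:
        raise ValueError("sd must be strictly positive")
    span = hi - lo
    if sd > span / 2:
        # Popoviciu bound: no distribution on [lo, hi] has SD > (hi-lo)/2
        raise InfeasibleMomentsError(
            f"SD {sd} exceeds the Popoviciu bound {span / 2} for any "
            f"distribution on [{lo}, {hi}]")

    def sd_at(sigma):
        return truncated_normal_moments(
            _mu_for_mean(sigma, mean, lo, hi), sigma, lo, hi)[1]

    # SD is increasing in sigma up to a plateau; locate the supremum first.
    res = optimize.minimize_scalar(
        lambda ls: -sd_at(math.exp(ls)),
        bounds=(math.log(span / 200), math.log(200 * span)),
        method="bounded", options={"xatol": 1e-8})
    sigma_top = math.exp(res.x)
    sd_top = -res.fun
    if sd >= sd_top:
        if abs(sd_top - sd) > rel_tol * sd and strict:
            raise InfeasibleMomentsError(
                f"requested SD {sd} exceeds the maximum {sd_top:.6g} "
                f"attainable by a truncated normal on [{lo}, {hi}] "
                f"with mean {mean}", achieved=sd_top)
        sigma = sigma_top
    else:
        sigma = optimize.brentq(lambda s: sd_at(s) - sd,
                                span / 200, sigma_top, xtol=1e-9 * span)
    mu = _mu_for_mean(sigma, mean, lo, hi)
    if strict:
        m_chk, s_chk = truncated_normal_moments(mu, sigma, lo, hi)
        if abs(m_chk - mean) > rel_tol * abs(mean) or \
                abs(s_chk - sd) > rel_tol * sd:
            raise InfeasibleMomentsError(
                f"truncated-normal fit missed targets: got mean={m_chk:.6g} "
                f"sd={s_chk:.6g}, wanted mean={mean} sd={sd}", achieved=s_chk)
    return mu, sigma


def _sample_truncnorm(rng, mu, sigma, lo, hi, n):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n,
                               random_state=rng)


def sample_isis(spec: ConditionSpec, n: int, seed: int | None = None,
                strict: bool = False) -> np.ndarray:
    """Draw ``n`` interspike intervals (s) for a condition.

    Values come from a normal law truncated to [isi_min, isi_max] with
    location/scale solved so the truncated mean equals ``isi_mean`` exactly
    and the truncated SD is as close to ``isi_sd`` as the family allows
    (see :func:`fit_truncated_normal`). Non-finite bounds disable truncation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if np.isinf(spec.isi_min) and np.isinf(spec.isi_max):
        return rng.normal(spec.isi_mean, spec.isi_sd, size=n)
    mu, sigma = fit_truncated_normal(spec.isi_mean, spec.isi_sd,
                                     spec.isi_min, spec.isi_max,
                                     strict=strict)
    return _sample_truncnorm(rng, mu, sigma, spec.isi_min, spec.isi_max, n)


# ---------------------------------------------------------------------------
# trace rendering
# ---------------------------------------------------------------------------

#: biexponential pulse time constants (s); the source study never specifies a
#: waveform shape, so a conventional fast-rise/slow-decay pulse is used.
PULSE_RISE_S = 5.0
PULSE_DECAY_S = 20.0


def _pulse_kernel(dt: float, rise: float = PULSE_RISE_S,
                  decay: float = PULSE_DECAY_S) -> tuple[np.ndarray, int]:
    """Unit-peak biexponential pulse sampled at dt; returns (kernel, peak_idx)."""
    t_peak = rise * decay / (decay - rise) * math.log(decay / rise)
    t_end = t_peak + decay * math.log(1e4)  # decay to 1e-4 of peak
    t = np.arange(0.0, t_end, dt)
    shape = np.exp(-t / decay) - np.exp(-t / rise)
    peak = math.exp(-t_peak / decay) - math.exp(-t_peak / rise)
    kernel = shape / peak
    return kernel, int(round(t_peak / dt))


def render_trace(events: SpikeEventList, duration: float,
                 spec: ConditionSpec, seed: int | None = None) -> Trace:
    """Render spike events into a uniformly sampled voltage trace (mV).

    Each event contributes a biexponential pulse whose rendered peak equals
    its amplitude (the pulse is time-shifted so the peak lands on the event
    time); pulses closer than the pulse width simply sum. A sinusoidal drift
    of amplitude ``spec.drift_amplitude`` and period ``spec.drift_period``
    plus white noise of SD ``spec.noise_sd`` are added. With zero noise and
    drift the baseline between spikes is exactly 0.
    """
    dt = spec.sample_interval
    n = int(round(duration / dt)) + 1
    if len(events) and events.times[-1] >= duration:
        raise ValueError("all event times must be < duration")
    values = np.zeros(n)
    if len(events):
        kernel, peak_idx = _pulse_kernel(dt)
        for t_ev, amp in zip(events.times, events.amplitudes):
            start = int(round(t_ev / dt)) - peak_idx
            k0 = max(-start, 0)
            s0 = max(start, 0)
            klen = min(kernel.size - k0, n - s0)
            if klen > 0:
                values[s0:s0 + klen] += amp * kernel[k0:k0 + klen]
    t = dt * np.arange(n)
    if spec.drift_amplitude > 0:
        values += spec.drift_amplitude * np.sin(
            2 * np.pi * t / spec.drift_period)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        values += rng.normal(0.0, spec.noise_sd, size=n)
    return Trace(values, dt=dt, unit="mV", label=spec.label)


def generate_condition_trace(spec: ConditionSpec, n_spikes: int,
                             seed: int | None = None,
                             lead_s: float = 200.0,
                             tail_s: float = 300.0
                             ) -> tuple[Trace, SpikeEventList]:
    """Sample a full condition-calibrated voltage trace plus ground truth.

    Spike times are the cumulative sum of sampled ISIs offset by ``lead_s``;
    independent substreams (derived from one seed) drive ISIs, amplitudes and
    noise so the trace is reproducible bit-for-bit.
    """
    base = np.random.SeedSequence(
        spec.seed if seed is None else seed).spawn(3)
    isi_seed, amp_seed, noise_seed = (s.generate_state(1)[0] for s in base)
    isis = sample_isis(spec, n_spikes, seed=int(isi_seed))
    amps = sample_amplitudes(spec, n_spikes, seed=int(amp_seed))
    times = lead_s + np.cumsum(isis)
    events = SpikeEventList(times=times, amplitudes=amps)
    duration = times[-1] + tail_s
    trace = render_trace(events, duration, spec, seed=int(noise_seed))
    return trace, events


# ---------------------------------------------------------------------------
# chronoamperometric current traces
# ---------------------------------------------------------------------------

def generate_current_trace(label: str, duration: float,
                           seed: int | None = None,
                           sample_interval: float = 1.0,
                           spike_rate: float = 0.02,
                           spike_scale: float = 0.25,
                           relax_tau: float = 0.5,
                           noise_sd: float = 0.0) -> Trace:
    """Generate a memristive chronoamperometric current trace (uA).

    A constant condition-dependent baseline (taken from the published mean
    currents, so vapour exposures sit above control and direct solvation
    below it) carries Poisson-arriving transient conductivity spikes with
    exponential relaxation of time constant ``relax_tau`` (subsecond by
    default). ``spike_rate`` is the arrival rate (1/s); transient peak sizes
    are exponentially distributed with mean ``spike_scale`` times baseline.
    ``spike_rate=0`` yields a constant baseline.
    """
    if duration < 10:
        raise ValueError("duration must be >= 10 s")
    if label not in CURRENT_BASELINE_UA:
        raise KeyError(f"unknown condition {label!r}; "
                       f"known: {list(CURRENT_BASELINE_UA)}")
    baseline = CURRENT_BASELINE_UA[label]
    dt = sample_interval
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    values = np.full(n, baseline)
    rng = np.random.default_rng(seed)
    if spike_rate > 0:
        n_events = rng.poisson(spike_rate * duration)
        ev_times = np.sort(rng.uniform(0.0, duration, size=n_events))
        ev_amps = rng.exponential(spike_scale * baseline, size=n_events)
        for t_ev, amp in zip(ev_times, ev_amps):
            i0 = int(np.ceil(t_ev / dt))
            i1 = min(n, i0 + int(np.ceil(12 * relax_tau / dt)) + 1)
            if i0 < n:
                values[i0:i1] += amp * np.exp(-(t[i0:i1] - t_ev) / relax_tau)
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=n)
    return Trace(values, dt=dt, unit="uA", label=label)
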