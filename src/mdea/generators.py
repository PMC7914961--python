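"""Surrogate time-series generators.

Three families of single-channel signals, all on an integer tick grid
(dt = 1):

* **Crucial-event trains** — renewal processes whose waiting times follow
  the hyperbolic inverse-power-law (IPL) density

      psi(tau) = (mu - 1) * T**(mu - 1) / (tau + T)**mu,   1 < mu < 3,

  optionally turned into a +/-W signal by filling each laminar region
  (the stretch between consecutive events) with the outcome of a fair
  coin toss.

* **Fractional Gaussian noise (fGn)** — the stationary increment process
  of fractional Brownian motion with Hurst exponent H, so the cumulative
  sum X(t) satisfies <X^2(t)> ~ t^(2H).  The default synthesis is exact
  circulant embedding of the fGn autocovariance; a Mandelbrot-van Ness
  weighted-sum construction and a band-limited spectral superposition of
  cosines (spectral density rho(omega) ~ omega^(eta-1), eta = 2 - 2H)
  are provided as independent alternatives.

* **Subordinated series** — fGn increments generated in operational time
  n and assigned to the clock times t(n) of a crucial-event train, with
  zeros in between.  This couples long-range Gaussian memory to the
  renewal (crucial-event) clock.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

logger = logging.getLogger("mdea.generators")

__all__ = [
    "RenewalParams",
    "FbmParams",
    "EventTrain",
    "FluctuationSeries",
    "sample_waiting_time",
    "generate_event_train",
    "fill_laminar_coin_toss",
    "fgn_autocovariance",
    "generate_fgn",
    "generate_fgn_spectral",
    "subordinate",
    "combined_series",
]


# ---------------------------------------------------------------------------
# Parameter and data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenewalParams:
    """Parameters of the IPL renewal (crucial-event) process.

    mu     : IPL index of the waiting-time density, must exceed 1 for the
             density to be normalizable; the complexity regime is 1 < mu < 3.
    T      : waiting-time scale in ticks (> 0).
    length : total number of ticks of the series.
    seed   : RNG seed.
    """

    mu: float
    T: float = 1.0
    length: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu > 1:
            raise ValueError(f"mu must be > 1 (got {self.mu})")
        if not self.T > 0:
            raise ValueError(f"T must be > 0 (got {self.T})")
        if int(self.length) < 1:
            raise ValueError(f"length must be >= 1 (got {self.length})")


@dataclass(frozen=True)
class FbmParams:
    """Parameters of the fGn/fBm generator.

    H      : Hurst exponent, 0 < H < 1.
    length : number of ticks.
    seed   : RNG seed.
    method : "circulant" (exact embedding, default), "mandelbrot_vanness"
             (truncated moving-average construction) or "spectral".
    """

    H: float
    length: int = 1_000_000
    seed: int = 0
    method: str = "circulant"

    def __post_init__(self) -> None:
        if not 0 < self.H < 1:
            raise ValueError(f"H must lie in (0, 1) (got {self.H})")
        if int(self.length) < 1:
            raise ValueError(f"length must be >= 1 (got {self.length})")
        if self.method not in ("circulant", "mandelbrot_vanness", "spectral"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class EventTrain:
    """Strictly increasing integer event times on ``[0, length)``."""

    times: np.ndarray
    length: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.length:
                raise ValueError("event times must lie in [0, length)")

    @property
    def n_events(self) -> int:
        return int(self.times.size)


@dataclass
class FluctuationSeries:
    """A signal xi(t): one real value per tick."""

    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")

    @property
    def length(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# Crucial events
# ---------------------------------------------------------------------------

def sample_waiting_time(mu: float, T: float, u):
    """Map uniform variates ``u`` in (0, 1) to IPL waiting times.

    Inverts the survival function Psi(tau) = (T / (T + tau))**(mu - 1):

        tau = T * (u**(-1 / (mu - 1)) - 1),

    so that under uniform ``u`` the returned waiting times have density
    psi(tau) = (mu - 1) T**(mu - 1) / (tau + T)**mu.  Accepts scalars or
    arrays.
    """
    if not mu > 1:
        raise ValueError(f"mu must be > 1 (got {mu})")
    if not T > 0:
        raise ValueError(f"T must be > 0 (got {T})")
    u_arr = np.asarray(u, dtype=np.float64)
    if np.any(u_arr <= 0) or np.any(u_arr >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    tau = T * (u_arr ** (-1.0 / (mu - 1.0)) - 1.0)
    return tau if np.ndim(u) else float(tau)


def generate_event_train(params: RenewalParams) -> EventTrain:
    """Generate a crucial-event train on the integer tick grid.

    Real-valued waiting times are drawn by inverse transform and
    accumulated in continuous time, starting from t = 0 (the first event
    is drawn from the same density, with no aging preparation).  The
    event ticks are the floors of the accumulated times; when flooring
    produces a collision the later event is advanced by one tick so the
    train stays strictly increasing.  Generation stops at ``length``.
    """
    rng = np.random.default_rng(params.seed)
    length = int(params.length)
    # Expected tick rate: 1/<tau> for mu > 2, sub-linear growth for mu <= 2.
    if params.mu > 2.05:
        mean_tau = params.T / (params.mu - 2.0)
        block = max(1024, int(1.2 * length / mean_tau))
    else:
        block = max(1024, int(2.0 * length ** max(params.mu - 1.0, 0.5)))

    cum_parts = []
    total = 0.0
    while total < length:
        u = rng.random(block)
        # rng.random may return exactly 0.0; the open-interval inverse
        # transform needs u in (0, 1).
        u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
        taus = params.T * (u ** (-1.0 / (params.mu - 1.0)) - 1.0)
        cum = total + np.cumsum(taus)
        cum_parts.append(cum)
        total = float(cum[-1])
        block = max(1024, block // 4)

    times_real = np.concatenate(cum_parts)
    times_real = times_real[times_real < length]
    if times_real.size == 0:
        return EventTrain(times=np.empty(0, dtype=np.int64), length=length)

    ticks = np.floor(times_real).astype(np.int64)
    # Strictly increasing repair: s_i = max(ticks_i, s_{i-1} + 1), done
    # vectorized via the running maximum of ticks_i - i.
    idx = np.arange(ticks.size, dtype=np.int64)
    ticks = np.maximum.accumulate(ticks - idx) + idx
    ticks = ticks[ticks < length]
    return EventTrain(times=ticks, length=length)


def fill_laminar_coin_toss(train: EventTrain, W: float = 1.0,
                           seed: int = 0) -> FluctuationSeries:
    """Fill each laminar region with +W or -W by a fair coin toss.

    The regions are: before the first event, between consecutive events,
    and from the last event to the end of the series.  Each region gets
    an independent fair-coin sign.
    """
    if not W > 0:
        raise ValueError(f"W must be > 0 (got {W})")
    rng = np.random.default_rng(seed)
    bounds = np.concatenate(([0], train.times, [train.length]))
    widths = np.diff(bounds)
    signs = W * (2.0 * rng.integers(0, 2, size=widths.size) - 1.0)
    values = np.repeat(signs, widths)
    return FluctuationSeries(values=values,
                             params={"kind": "coin_toss", "W": W})


# ---------------------------------------------------------------------------
# Fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocovariance(H: float, lags) -> np.ndarray:
    """Autocovariance of unit-variance fGn:

    gamma(k) = 1/2 (|k+1|^(2H) - 2|k|^(2H) + |k-1|^(2H)).
    """
    k = np.abs(np.asarray(lags, dtype=np.float64))
    return 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H)
                  + np.abs(k - 1) ** (2 * H))


def _fgn_circulant(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact circulant-embedding (Davies-Harte) synthesis of fGn."""
    if n == 1:
        return rng.standard_normal(1)
    m = 2 * n
    gamma = fgn_autocovariance(H, np.arange(n + 1))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eigs = np.fft.fft(row).real
    if eigs.min() < -1e-8 * eigs.max():
        # The fGn embedding is nonnegative-definite in exact arithmetic;
        # a materially negative eigenvalue signals round-off trouble.
        # Clip and continue with the (approximate) truncated spectrum.
        logger.warning("circulant embedding produced negative eigenvalue "
                       "%.3e; clipping to zero (approximate synthesis)",
                       eigs.min())
    eigs = np.clip(eigs, 0.0, None)
    # z has E|z_k|^2 = 2, so the spectral weights need lambda_k / m for
    # the real part to carry the full target covariance.
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(eigs / m) * z)
    return x.real[:n]


def _fgn_mandelbrot_vanness(H: float, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Truncated Mandelbrot-van Ness moving-average synthesis of fGn.

    Builds fBm as a power-law weighted sum over a white-noise history,

        B_H(t) ~ sum_{k < t} [ (t-k)^(H-1/2) - max(-k, 0)^(H-1/2) ] xi_k,

    with the history truncated ``burn`` ticks into the past, then takes
    increments and rescales by the exact (deterministic) standard
    deviation of the truncated construction.  Approximate (the
    truncation slightly distorts the longest correlations); kept as an
    independent cross-check of the exact circulant method.
    """
    burn = max(4 * n, 1024)
    total = burn + n
    xi = rng.standard_normal(total)
    # Bin-integrated kernel: v_j = integral of s^(H-1/2) over [j-1, j].
    # Integrating over the white-noise bins (rather than sampling the
    # kernel pointwise) keeps the short-lag covariance accurate despite
    # the kernel's singularity at s -> 0.
    j = np.arange(0, total + 1, dtype=np.float64)
    V = j ** (H + 0.5) / (H + 0.5)
    kernel = np.diff(V)
    conv = fftconvolve(xi, kernel)[: total]
    # B(t) for t = 0..n: conv index t + burn - 1; subtract the constant
    # history term so that B(0) = 0.
    hist = np.dot(kernel[:burn][::-1], xi[:burn])
    B = np.empty(n + 1)
    B[0] = 0.0
    B[1:] = conv[burn: burn + n] - hist
    out = np.diff(B)
    # Exact variance of the t-th increment of the truncated construction:
    # v_1^2 + sum_{j <= t+burn-1} (v_{j+1} - v_j)^2.
    dw2 = np.cumsum((kernel[1:] - kernel[:-1]) ** 2)
    sd = np.sqrt(kernel[0] ** 2 + dw2[burn - 1: burn + n - 1])
    return out / sd


def generate_fgn(params: FbmParams) -> FluctuationSeries:
    """Generate unit-variance fractional Gaussian noise.

    The cumulative sum of the returned series is fBm with the requested
    Hurst exponent: <X^2(n)> ~ n^(2H).  Method "circulant" is exact in
    the autocovariance; "mandelbrot_vanness" is the truncated
    moving-average construction, "spectral" a band-limited cosine
    superposition (see :func:`generate_fgn_spectral`).
    """
    rng = np.random.default_rng(params.seed)
    n = int(params.length)
    if params.method == "circulant":
        values = _fgn_circulant(params.H, n, rng)
    elif params.method == "mandelbrot_vanness":
        values = _fgn_mandelbrot_vanness(params.H, n, rng)
    else:
        return generate_fgn_spectral(params, n_modes=1000)
    return FluctuationSeries(values=values,
                             params={"kind": "fgn", "H": params.H,
                                     "method": params.method})


def generate_fgn_spectral(params: FbmParams, n_modes: int = 1000,
                          band: tuple[float, float] | None = None,
                          ) -> FluctuationSeries:
    """Superpose cosines with power-law distributed frequencies.

    Frequencies are drawn on ``band`` (default ``[2*pi/length, pi]``)
    with density rho(omega) ~ omega^(eta - 1), eta = 2 - 2H, and each
    mode gets an independent uniform phase.  The ensemble autocorrelation
    decays as t^(-eta) inside the band-limited regime; the series is
    normalized so that a single mode set has unit ensemble variance.
    """
    if n_modes < 0:
        raise ValueError("n_modes must be >= 0")
    n = int(params.length)
    if n_modes == 0:
        logger.warning("n_modes=0: returning the zero series")
        return FluctuationSeries(values=np.zeros(n),
                                 params={"kind": "fgn_spectral",
                                         "H": params.H, "n_modes": 0})
    eta = 2.0 - 2.0 * params.H
    if not 0 < eta < 2:
        raise ValueError(f"eta = 2 - 2H must lie in (0, 2) (got {eta})")
    lo, hi = band if band is not None else (2.0 * np.pi / n, np.pi)
    if not 0 < lo < hi:
        raise ValueError(f"invalid frequency band ({lo}, {hi})")
    rng = np.random.default_rng(params.seed)
    u = rng.random(n_modes)
    # Inverse CDF of rho(w) ~ w^(eta-1) on [lo, hi].
    omega = (lo ** eta + u * (hi ** eta - lo ** eta)) ** (1.0 / eta)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
    t = np.arange(n, dtype=np.float64)
    values = np.zeros(n)
    chunk = max(1, int(4e6) // max(n, 1))
    for start in range(0, n_modes, chunk):
        w = omega[start:start + chunk, None]
        p = phase[start:start + chunk, None]
        values += np.cos(w * t[None, :] + p).sum(axis=0)
    values *= np.sqrt(2.0 / n_modes)
    return FluctuationSeries(values=values,
                             params={"kind": "fgn_spectral", "H": params.H,
                                     "n_modes": n_modes,
                                     "band": (float(lo), float(hi))})


# ---------------------------------------------------------------------------
# Subordination
# ---------------------------------------------------------------------------

def subordinate(increments: FluctuationSeries,
                train: EventTrain) -> FluctuationSeries:
    """Assign operational-time increments to the clock times of a train.

    ``output[t(n)] = increments[n]`` for the n-th event; every non-event
    tick is zero.  The increments are consumed in operational-time order.
    """
    n_events = train.n_events
    if n_events > increments.length:
        raise ValueError(
            f"train has {n_events} events but only {increments.length} "
            "increments are available")
    values = np.zeros(train.length)
    values[train.times] = increments.values[:n_events]
    return FluctuationSeries(values=values,
                             params={"kind": "subordinated",
                                     **increments.params})


def combined_series(mu: float, H: float, T: float = 1.0,
                    length: int = 1_000_000, seed: int = 0,
                    ) -> FluctuationSeries:
    """fGn increments subordinated to a crucial-event clock.

    Draws independent sub-streams for the renewal waiting times and the
    Gaussian increments from one master seed, generates exactly as many
    fGn increments (in operational time) as the train has events, and
    subordinates them.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    train = generate_event_train(
        RenewalParams(mu=mu, T=T, length=length,
                      seed=ss[0].generate_state(1)[0] % (2 ** 31)))
    if train.n_events == 0:
        return FluctuationSeries(values=np.zeros(int(length)),
                                 params={"kind": "subordinated", "mu": mu,
                                         "H": H})
    incs = generate_fgn(FbmParams(H=H, length=train.n_events,
                                  seed=ss[1].generate_state(1)[0] % (2 ** 31)))
    out = subordinate(incs, train)
    out.params.update({"mu": mu, "T": T, "H": H})
    return out
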