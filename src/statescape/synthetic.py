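"""Synthetic signals and multichannel regime surrogates.

Two families of generators live here. The first produces analytically
tractable univariate signals (sinusoids, logistic-map orbits, AR(1) noise)
and planar circle clouds, used as ground truth for the ordinal, spectral
and topological machinery. The second emulates short multichannel
electrophysiological segments in three dynamical regimes ordered by
"richness":

``rich``
    weakly coupled chaotic broadband channels with 1/f background —
    a stand-in for awake cortical activity;
``poor``
    a single shared slow (~2 Hz) oscillation projected to every channel
    with small independent noise — a stand-in for deep sedation;
``intermediate``
    an equal per-channel mixture of the two.

The surrogates are operational, not biophysical: they are constructed so
that entropy-like measures (ordinal repertoire, permutation entropy,
homological cycle counts, Lyapunov exponent) decrease from ``rich`` to
``poor`` while determinism and state-transition modularity increase, the
qualitative signature the pipeline is designed to resolve.

All generators take explicit integer seeds and never touch global random
state; the same seed yields bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segment import RecordingSegment

__all__ = [
    "RegimeSpec",
    "gen_sine",
    "gen_logistic",
    "gen_ar1",
    "gen_pink_noise",
    "gen_circle_cloud",
    "gen_regime",
]

REGIMES = ("rich", "intermediate", "poor")


@dataclass(frozen=True)
class RegimeSpec:
    """Parameters of a multichannel regime surrogate.

    ``coupling`` in [0, 1] mixes each channel's private source with a
    shared one; ``noise_scale`` is the SD of independent white noise added
    per channel (signals are generated at unit scale).
    """

    regime: str
    n_channels: int = 16
    duration_s: float = 10.0
    fs: float = 250.0
    coupling: float = 0.1
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration_s * fs = {n} is not an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def gen_sine(freq: float, fs: float, n: int, amplitude: float = 1.0, phase: float = 0.0) -> np.ndarray:
    """Sampled sinusoid ``amplitude * sin(2 pi freq t / fs + phase)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < freq < fs / 2:
        raise ValueError(f"freq must lie in (0, fs/2) = (0, {fs / 2}); got {freq} (Nyquist limit)")
    t = np.arange(n)
    return amplitude * np.sin(2.0 * np.pi * freq * t / fs + phase)


def gen_logistic(r: float, x0: float, n: int) -> np.ndarray:
    """Orbit of the logistic map ``x -> r x (1 - x)``.

    At ``r = 4`` the map is fully chaotic with largest Lyapunov exponent
    ln 2 and an arcsine invariant density; it is the reference fixture for
    the Lyapunov estimator.
    """
    if not 0 < r <= 4:
        raise ValueError(f"r must lie in (0, 4], got {r}")
    if not 0 < x0 < 1:
        raise ValueError(f"x0 must lie in (0, 1), got {x0}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if r == 4 and x0 in (0.5,):
        warnings.warn("x0=0.5 with r=4 collapses to the fixed point 0 after two steps", stacklevel=2)
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    return x


def gen_ar1(phi: float, sigma: float, n: int, seed: int, x0: float = 0.0) -> np.ndarray:
    """Stationary AR(1) process ``x[t+1] = phi x[t] + Normal(0, sigma^2)``."""
    if abs(phi) >= 1:
        raise ValueError(f"|phi| must be < 1 for stationarity, got {phi}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=n)
    x = np.empty(n)
    x[0] = x0 + eps[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x


def gen_pink_noise(n: int, seed: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * scale, n=n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def gen_circle_cloud(n: int, radius: float = 1.0, noise: float = 0.0, seed: int = 0) -> np.ndarray:
    """``n`` angle-uniform points on a circle plus isotropic Gaussian noise."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    theta = 2.0 * np.pi * np.arange(n) / n
    pts = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    if noise > 0:
        pts = pts + np.random.default_rng(seed).normal(0.0, noise, size=pts.shape)
    return pts


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


#: Hann smoothing width (samples) of the broadband chaotic source
_CHAOS_SMOOTH = 5


def _chaotic_channel(rng: np.random.Generator, n: int) -> np.ndarray:
    """Standardized broadband chaotic source.

    A fully chaotic logistic orbit (random initial state, burn-in 100
    steps) smoothed with a short Hann window: the smoothing spreads the
    map's divergence over a few samples so the series has a broadband but
    temporally correlated spectrum, as fast cortical activity does,
    instead of white-noise-like sample-to-sample chaos.
    """
    x0 = rng.uniform(0.05, 0.95)
    orbit = gen_logistic(4.0, x0, n + 100 + _CHAOS_SMOOTH)[100:]
    w = np.hanning(_CHAOS_SMOOTH + 2)[1:-1]
    return _standardize(np.convolve(orbit, w / w.sum(), mode="valid")[:n])


def _slow_oscillation(rng: np.random.Generator, n: int, fs: float, f0: float = 2.0) -> np.ndarray:
    """Amplitude-modulated slow oscillation shared across channels."""
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    mod_phase = rng.uniform(0.0, 2.0 * np.pi)
    am = 1.0 + 0.2 * np.sin(2.0 * np.pi * 0.3 * t + mod_phase)
    return _standardize(am * np.sin(2.0 * np.pi * f0 * t + phase))


def gen_regime(spec: RegimeSpec) -> RecordingSegment:
    """Generate a multichannel surrogate segment for one dynamical regime.

    Channel construction (all sources standardized to unit SD first):

    - ``rich``: ``(1-coupling) * private_chaos + coupling * shared_chaos
      + 0.2 * pink + noise_scale * white`` per channel;
    - ``poor``: ``gain_c * shared_slow + noise_scale * white`` with
      per-channel gains drawn from U(0.5, 1.5);
    - ``intermediate``: equal mixture of a rich-style and a poor-style
      channel, plus the same white noise term.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    c = spec.n_channels
    data = np.empty((c, n))

    if spec.regime in ("rich", "intermediate"):
        shared_chaos = _chaotic_channel(rng, n)
    if spec.regime in ("poor", "intermediate"):
        shared_slow = _slow_oscillation(rng, n, spec.fs)

    for ch in range(c):
        if spec.regime == "rich":
            sig = (1.0 - spec.coupling) * _chaotic_channel(rng, n) + spec.coupling * shared_chaos
            sig = sig + 0.2 * gen_pink_noise(n, int(rng.integers(2**31)))
        elif spec.regime == "poor":
            sig = rng.uniform(0.5, 1.5) * shared_slow
        else:  # intermediate
            fast = (1.0 - spec.coupling) * _chaotic_channel(rng, n) + spec.coupling * shared_chaos
            fast = fast + 0.2 * gen_pink_noise(n, int(rng.integers(2**31)))
            sig = 0.5 * fast + 0.5 * rng.uniform(0.5, 1.5) * shared_slow
        if spec.noise_scale > 0:
            sig = sig + spec.noise_scale * rng.standard_normal(n)
        data[ch] = sig

    return RecordingSegment(
        data=data,
        fs=spec.fs,
        subject=f"synthetic-seed{spec.seed}",
        condition=f"synthetic-{spec.regime}",
        history=[f"gen_regime({spec!r})"],
    )
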