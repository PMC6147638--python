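"""MEG-like multichannel signal generator with planted coupling.

Each channel is a sum of band-limited oscillations: a slow positive
amplitude envelope times a carrier inside the band, plus Gaussian sensor
noise. Coupling is planted at the envelope (amplitude-amplitude) level —
two node-layers that should coordinate share an envelope component — plus
optional theta-phase/gamma-amplitude modulation. The planted structure is
returned alongside the signals so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from freqlayer.bands import ALPHA, FrequencyBand, THETA
from freqlayer.timeseries import TimeSeriesSet

__all__ = [
    "SyntheticSignalConfig",
    "GroundTruth",
    "generate_signals",
]

# Stream tags keep per-channel/band RNG streams disjoint so adding a channel
# or a coupling never perturbs the other streams.
_STREAM_ENVELOPE = 1
_STREAM_PHASE = 2
_STREAM_NOISE = 3
_STREAM_SHARED_INTRA = 4
_STREAM_SHARED_CROSS = 5
_STREAM_CARRIER = 6


@dataclass
class SyntheticSignalConfig:
    """Parameters of the synthetic signal generator.

    Coupling lists:

    - ``intra_band_pairs``: ``(i, j, band_name, rho)`` — channels i and j
      share an envelope component in one band with mixing weight rho.
    - ``cross_band_pairs``: ``(i, band_name, j, band_name2, rho)`` — channel
      i's envelope in one band shares a component with channel j's envelope
      in another band.
    - ``pac_pairs``: ``(theta_source, gamma_target, kappa)`` — the gamma
      envelope of the target is modulated by ``1 + kappa * sin(theta phase)``
      of the source.

    A given (channel, band) node-layer may appear in at most one coupling
    pair so the planted truth is unambiguous.
    """

    n_channels: int
    bands: tuple[FrequencyBand, ...] = (THETA, ALPHA)
    sampling_rate: float = 508.63
    n_samples: int = 20000
    carriers: dict[str, float] = field(default_factory=dict)
    carrier_jitter: float = 0.3
    envelope_cutoff: float = 1.0
    intra_band_pairs: list[tuple[int, int, str, float]] = field(default_factory=list)
    cross_band_pairs: list[tuple[int, str, int, str, float]] = field(default_factory=list)
    pac_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be positive, got {self.n_samples}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.envelope_cutoff <= 0:
            raise ValueError("envelope_cutoff must be positive")
        if not 0 <= self.carrier_jitter < 1:
            raise ValueError("carrier_jitter must be in [0, 1)")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("duplicate band names")
        for b in self.bands:
            f = self.carrier_for(b)
            if not b.contains(f, strict=True):
                raise ValueError(
                    f"carrier {f} Hz is not strictly inside band "
                    f"{b.name} [{b.low}, {b.high}]"
                )
        self._validate_pairs(names)

    def _validate_pairs(self, band_names: list[str]) -> None:
        seen: set[tuple[int, str]] = set()

        def claim(ch: int, band: str) -> None:
            if not 0 <= ch < self.n_channels:
                raise ValueError(f"channel {ch} out of range")
            if band not in band_names:
                raise ValueError(f"unknown band {band!r} in coupling pair")
            if (ch, band) in seen:
                raise ValueError(
                    f"node-layer (channel {ch}, band {band!r}) appears in "
                    "more than one coupling pair"
                )
            seen.add((ch, band))

        for i, j, band, rho in self.intra_band_pairs:
            if not 0 <= rho <= 1:
                raise ValueError(f"rho_intra={rho} outside [0, 1]")
            claim(i, band)
            claim(j, band)
        for i, bi, j, bj, rho in self.cross_band_pairs:
            if not 0 <= rho <= 1:
                raise ValueError(f"rho_cross={rho} outside [0, 1]")
            claim(i, bi)
            claim(j, bj)
        for src, tgt, kappa in self.pac_pairs:
            if not 0 <= kappa <= 1:
                raise ValueError(f"kappa={kappa} outside [0, 1]")
            if not (0 <= src < self.n_channels and 0 <= tgt < self.n_channels):
                raise ValueError("PAC pair channel out of range")

    def carrier_for(self, band: FrequencyBand) -> float:
        return self.carriers.get(band.name, band.midpoint)

    def band_index(self, name: str) -> int:
        for k, b in enumerate(self.bands):
            if b.name == name:
                return k
        raise KeyError(name)


@dataclass(frozen=True)
class GroundTruth:
    """The planted coupled node-layer pairs with their coupling weights."""

    intra_band: tuple[tuple[int, int, str, float], ...]
    cross_band: tuple[tuple[int, str, int, str, float], ...]
    pac: tuple[tuple[int, int, float], ...]

    def coupled_node_layers(self) -> list[tuple[tuple[int, str], tuple[int, str], float]]:
        """All planted pairs as ((channel, band), (channel, band), weight)."""
        out = []
        for i, j, band, rho in self.intra_band:
            out.append(((i, band), (j, band), rho))
        for i, bi, j, bj, rho in self.cross_band:
            out.append(((i, bi), (j, bj), rho))
        for src, tgt, kappa in self.pac:
            out.append(((src, "theta"), (tgt, "gamma"), kappa))
        return out


def _rng(config: SyntheticSignalConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *key]))


def _envelope_stream(
    rng: np.random.Generator, n: int, fs: float, cutoff: float
) -> np.ndarray:
    """Positive slow *stationary* process with unit mean.

    Absolute value of low-pass-filtered white Gaussian noise, rescaled to
    mean 1. Stationarity matters: envelopes built on random walks carry
    record-long trends, and two independent trends are spuriously dependent
    in-sample, which inflates the MI of uncoupled channels far above its
    surrogate threshold.
    """
    # Generate with margins and trim them: the filter's edge transient is a
    # *common* time-locked amplitude profile across channels, which would
    # register as spurious cross-channel dependence downstream.
    margin = int(4 * fs / cutoff)
    noise = rng.standard_normal(n + 2 * margin)
    b, a = scipy.signal.butter(2, cutoff, btype="low", fs=fs)
    padlen = min(noise.size - 1, 3 * max(len(a), len(b)))
    env = np.abs(scipy.signal.filtfilt(b, a, noise, padlen=padlen))
    env = env[margin:margin + n]
    mean = env.mean()
    if mean <= 0:  # degenerate only for pathological lengths
        return np.ones(n)
    return env / mean


def generate_signals(config: SyntheticSignalConfig) -> tuple[TimeSeriesSet, GroundTruth]:
    """Generate signals plus the planted coupling ground truth.

    Channel ``n`` is ``sum_b a_nb(t) cos(2 pi f_b t + phi_nb) + noise`` with
    positive unit-mean envelopes ``a_nb``. A planted pair mixes a shared
    envelope component with weight rho: ``a = (1 - rho) e_own + rho e_shared``
    so rho=1 means identical envelopes and rho=0 fully independent ones.
    Identical config and seed give bit-identical output.
    """
    n, T = config.n_channels, config.n_samples
    fs = config.sampling_rate
    t = np.arange(T) / fs

    # independent per-node-layer envelopes
    envelopes = np.empty((n, len(config.bands), T))
    for ch in range(n):
        for bi in range(len(config.bands)):
            rng = _rng(config, _STREAM_ENVELOPE, ch, bi)
            envelopes[ch, bi] = _envelope_stream(rng, T, fs, config.envelope_cutoff)

    def mix(ch: int, bi: int, rho: float, shared: np.ndarray) -> None:
        envelopes[ch, bi] = (1.0 - rho) * envelopes[ch, bi] + rho * shared

    for k, (i, j, band, rho) in enumerate(config.intra_band_pairs):
        bi = config.band_index(band)
        shared = _envelope_stream(
            _rng(config, _STREAM_SHARED_INTRA, k), T, fs, config.envelope_cutoff
        )
        mix(i, bi, rho, shared)
        mix(j, bi, rho, shared)

    for k, (i, band_i, j, band_j, rho) in enumerate(config.cross_band_pairs):
        shared = _envelope_stream(
            _rng(config, _STREAM_SHARED_CROSS, k), T, fs, config.envelope_cutoff
        )
        mix(i, config.band_index(band_i), rho, shared)
        mix(j, config.band_index(band_j), rho, shared)

    # carrier phases and per-channel carrier frequencies (jittered within the
    # band so independent channels are not deterministically phase-locked)
    phases = np.empty((n, len(config.bands)))
    carriers = np.empty((n, len(config.bands)))
    for ch in range(n):
        for bi, band in enumerate(config.bands):
            phases[ch, bi] = _rng(config, _STREAM_PHASE, ch, bi).uniform(0, 2 * np.pi)
            base = config.carrier_for(band)
            half = min(base - band.low, band.high - base)
            jitter = _rng(config, _STREAM_CARRIER, ch, bi).uniform(-1.0, 1.0)
            carriers[ch, bi] = base + config.carrier_jitter * half * jitter

    # optional theta-phase -> gamma-amplitude modulation
    band_names = [b.name for b in config.bands]
    for src, tgt, kappa in config.pac_pairs:
        if "theta" not in band_names or "gamma" not in band_names:
            raise ValueError("PAC pairs require both theta and gamma bands")
        ti = band_names.index("theta")
        gi = band_names.index("gamma")
        theta_phase = 2 * np.pi * carriers[src, ti] * t + phases[src, ti]
        envelopes[tgt, gi] = envelopes[tgt, gi] * (1.0 + kappa * np.sin(theta_phase))

    values = np.zeros((n, T))
    for ch in range(n):
        for bi, band in enumerate(config.bands):
            values[ch] += envelopes[ch, bi] * np.cos(
                2 * np.pi * carriers[ch, bi] * t + phases[ch, bi]
            )
        if config.noise_sd > 0:
            values[ch] += config.noise_sd * _rng(
                config, _STREAM_NOISE, ch
            ).standard_normal(T)

    ts = TimeSeriesSet(values=values, sampling_rate=fs)
    truth = GroundTruth(
        intra_band=tuple(tuple(p) for p in config.intra_band_pairs),
        cross_band=tuple(tuple(p) for p in config.cross_band_pairs),
        pac=tuple(tuple(p) for p in config.pac_pairs),
    )
    return ts, truth
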