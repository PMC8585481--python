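"""Synthesis of 1/f^chi amplitude-modulated noise stimuli.

Stimuli consist of a broadband carrier (high-pass filtered white noise
for audition; a luminance series for vision) whose amplitude is
modulated by a random envelope with a power-law amplitude-modulation
(AM) spectrum, P(f) ∝ f^-chi.  Because modulation leaves the long-term
carrier spectrum untouched, stimuli of different AM exponents are
spectrally identical in the carrier band and differ only in the temporal
statistics of their envelopes.

Targets are brief (400 ms) sinusoidal AMs at 6-7.5 Hz cross-faded into
the noise envelope; their modulation depth controls detectability.

Trial-wise AM exponents are estimated by Welch spectral estimation of
the envelope (1-30 Hz, 0.1 Hz grid) followed by spectral
parameterization over 1-25 Hz (see :mod:`apertrack.specfit`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .specfit import PRESETS, SpectralFit, parameterize, welch_psd

__all__ = [
    "ModulatorSpec",
    "Envelope",
    "Stimulus",
    "make_modulator",
    "make_carrier",
    "modulate",
    "make_visual",
    "cut_trial",
    "embed_target",
    "stim_am_exponent",
]

VISUAL_RATE_HZ = 85.0
_ENV_ANALYSIS_RATE = 250.0  # envelopes are decimated to this rate before Welch


@dataclass(frozen=True)
class ModulatorSpec:
    chi: float
    duration_s: float
    sample_rate_hz: float
    lowpass_hz: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.chi < 0:
            raise ValueError("chi must be >= 0")
        if self.lowpass_hz >= self.sample_rate_hz / 2:
            raise ValueError("lowpass_hz must be below the Nyquist frequency")
        if self.n_samples < 2:
            raise ValueError("duration x sample rate must give at least 2 samples")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))


@dataclass(frozen=True)
class Envelope:
    """A non-negative amplitude-modulation time series in [0, 1]."""

    samples: np.ndarray
    sample_rate_hz: float
    spec: ModulatorSpec | None = None

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("envelope samples must be finite")
        if x.min() < -1e-9 or x.max() > 1 + 1e-9:
            raise ValueError("envelope samples must lie in [0, 1]")
        object.__setattr__(self, "samples", x)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


@dataclass(frozen=True)
class Stimulus:
    samples: np.ndarray
    sample_rate_hz: float
    modality: str  # "auditory" | "visual"
    envelope: np.ndarray | None = None  # AM series at the stimulus rate
    carrier: np.ndarray | None = None  # raw carrier (auditory only)
    chi_nominal: float | None = None
    chi_local: float | None = None
    target_onset_s: float | None = None
    target_freq_hz: float | None = None
    target_depth: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


def _rescale01(x: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Affine rescale to [lo, hi]; degenerate (constant) input maps to mid-range."""
    rng = x.max() - x.min()
    if rng == 0:
        return np.full_like(x, (lo + hi) / 2)
    return lo + (hi - lo) * (x - x.min()) / rng


def make_modulator(spec: ModulatorSpec) -> Envelope:
    """Random-phase power-law envelope: amplitude spectrum ∝ f^(-chi/2).

    The series is built in the frequency domain (DC = 0, uniform random
    phases), transformed with a real inverse FFT, low-pass filtered
    (zero-phase 4th-order Butterworth) and affinely rescaled to [0, 1],
    so its power spectrum falls as f^-chi below the cutoff.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate_hz)
    amp = np.zeros_like(freqs)
    nonzero = freqs > 0
    amp[nonzero] = freqs[nonzero] ** (-spec.chi / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    sos = sps.butter(4, spec.lowpass_hz, btype="low", fs=spec.sample_rate_hz, output="sos")
    x = sps.sosfiltfilt(sos, x)
    return Envelope(_rescale01(x), spec.sample_rate_hz, spec)


def make_carrier(duration_s: float, sample_rate_hz: float,
                 highpass_hz: float = 200.0, seed: int = 0) -> Stimulus:
    """Gaussian white-noise carrier, zero-phase high-pass filtered."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if highpass_hz >= sample_rate_hz / 2:
        raise ValueError("highpass_hz must be below the Nyquist frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    x = rng.standard_normal(n)
    sos = sps.butter(4, highpass_hz, btype="high", fs=sample_rate_hz, output="sos")
    x = sps.sosfiltfilt(sos, x)
    return Stimulus(x, sample_rate_hz, "auditory", carrier=x.copy(),
                    meta={"seed": seed, "highpass_hz": highpass_hz})


def _match_envelope(envelope: Envelope, sample_rate_hz: float, n: int) -> np.ndarray:
    env = envelope.samples
    if envelope.sample_rate_hz != sample_rate_hz:
        up = int(round(sample_rate_hz))
        down = int(round(envelope.sample_rate_hz))
        env = sps.resample_poly(env, up, down, padtype="line")
        env = np.clip(env, 0.0, 1.0)
    if abs(env.size - n) > max(2, 0.001 * n):
        raise ValueError("envelope and carrier lengths do not match after resampling")
    if env.size > n:
        env = env[:n]
    elif env.size < n:
        env = np.pad(env, (0, n - env.size), mode="edge")
    return env


def modulate(carrier: Stimulus, envelope: Envelope) -> Stimulus:
    """Multiply the carrier by the envelope and RMS-normalize to 1.0."""
    env = _match_envelope(envelope, carrier.sample_rate_hz, carrier.samples.size)
    raw = carrier.samples * env
    rms = np.sqrt(np.mean(raw**2))
    if rms == 0:
        raise ValueError("all-zero envelope: RMS normalization impossible")
    chi = envelope.spec.chi if envelope.spec is not None else None
    return Stimulus(
        raw / rms, carrier.sample_rate_hz, "auditory",
        envelope=env, carrier=carrier.samples.copy(),
        chi_nominal=chi, meta=dict(carrier.meta),
    )


def make_visual(envelope: Envelope) -> Stimulus:
    """Anti-aliased resample of the envelope to 85 Hz, rescaled to [0.5, 1].

    The visual stimulus IS its envelope: luminance variations of a disk at
    the 85 Hz display refresh rate.
    """
    if envelope.sample_rate_hz < 2 * VISUAL_RATE_HZ:
        raise ValueError("envelope sample rate must be at least 170 Hz")
    n_out = int(round(envelope.duration_s * VISUAL_RATE_HZ))
    if envelope.samples.max() - envelope.samples.min() == 0:
        chi0 = envelope.spec.chi if envelope.spec is not None else None
        const = np.full(n_out, 0.75)
        return Stimulus(const, VISUAL_RATE_HZ, "visual", envelope=const.copy(),
                        chi_nominal=chi0)
    up, down = int(round(VISUAL_RATE_HZ * 20)), int(round(envelope.sample_rate_hz * 20))
    from math import gcd
    g = gcd(up, down)
    env85 = sps.resample_poly(envelope.samples, up // g, down // g, padtype="line")
    env85 = env85[:n_out] if env85.size >= n_out else np.pad(env85, (0, n_out - env85.size), mode="edge")
    lum = _rescale01(env85, 0.5, 1.0)
    chi = envelope.spec.chi if envelope.spec is not None else None
    return Stimulus(lum, VISUAL_RATE_HZ, "visual", envelope=lum.copy(), chi_nominal=chi)


def cut_trial(long_stimulus: Stimulus, seed: int = 0,
              duration_range_s: tuple = (4.0, 4.5),
              estimate_chi: bool = True) -> Stimulus:
    """Cut a 4-4.5 s snippet at a seeded random offset.

    The snippet's own AM exponent (``chi_local``) generally differs from
    the parent's nominal exponent because short excerpts of a power-law
    envelope have variable local spectra — this is what produces the wide
    trial-wise distribution of AM exponents.
    """
    rng = np.random.default_rng(seed)
    fs = long_stimulus.sample_rate_hz
    dur = rng.uniform(*duration_range_s)
    if long_stimulus.duration_s < duration_range_s[1]:
        raise ValueError("source stimulus shorter than the maximum trial duration")
    n = int(round(dur * fs))
    start = rng.integers(0, long_stimulus.samples.size - n + 1)
    sl = slice(start, start + n)
    env = long_stimulus.envelope[sl] if long_stimulus.envelope is not None else None
    car = long_stimulus.carrier[sl] if long_stimulus.carrier is not None else None
    snip = Stimulus(
        long_stimulus.samples[sl], fs, long_stimulus.modality,
        envelope=env, carrier=car, chi_nominal=long_stimulus.chi_nominal,
        meta={**long_stimulus.meta, "cut_offset_s": start / fs, "cut_seed": seed},
    )
    if estimate_chi and env is not None:
        snip = replace(snip, chi_local=float(stim_am_exponent(snip).exponent))
    return snip


def _target_envelope(env: np.ndarray, fs: float, freq_hz: float, depth: float,
                     onset_s: float, duration_s: float, phase: float,
                     fade_s: float = 0.05) -> np.ndarray:
    """Blend the noise AM toward a sinusoidal AM inside the target window.

    The blend weight ramps on/off with 50 ms raised-cosine flanks and is
    scaled by the modulation depth, so depth 0 leaves the stimulus
    untouched and depth 1 cross-fades into a pure sinusoidal AM.
    """
    n = env.size
    i0, i1 = int(round(onset_s * fs)), int(round((onset_s + duration_s) * fs))
    t = np.arange(i0, i1) / fs
    sin_env = 0.5 * (1.0 + np.sin(2 * np.pi * freq_hz * (t - onset_s) + phase))
    w = np.ones(i1 - i0)
    n_fade = min(int(round(fade_s * fs)), (i1 - i0) // 2)
    if n_fade > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        w[:n_fade] = ramp
        w[-n_fade:] = ramp[::-1]
    out = env.copy()
    out[i0:i1] = (1 - depth * w) * env[i0:i1] + depth * w * sin_env
    return out


def embed_target(stimulus: Stimulus, freq_hz: float, depth: float, onset_s: float,
                 duration_s: float = 0.4, seed: int = 0) -> Stimulus:
    """Embed a brief sinusoidal AM target into the stimulus envelope."""
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    if onset_s + duration_s > stimulus.duration_s + 1e-9:
        raise ValueError("target window extends beyond the stimulus")
    if depth == 0.0:
        return replace(stimulus, target_onset_s=onset_s, target_freq_hz=freq_hz,
                       target_depth=0.0)
    if stimulus.envelope is None:
        raise ValueError("stimulus carries no envelope to modulate")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    fs = stimulus.sample_rate_hz
    if stimulus.modality == "visual":
        # luminance lives in [0.5, 1]: map to [0,1], blend, map back
        env01 = (stimulus.envelope - 0.5) / 0.5
        new01 = _target_envelope(env01, fs, freq_hz, depth, onset_s, duration_s, phase)
        new = 0.5 + 0.5 * new01
        return replace(stimulus, samples=new, envelope=new,
                       target_onset_s=onset_s, target_freq_hz=freq_hz, target_depth=depth)
    if stimulus.carrier is None:
        raise ValueError("auditory stimulus carries no carrier for re-modulation")
    new_env = _target_envelope(stimulus.envelope, fs, freq_hz, depth,
                               onset_s, duration_s, phase)
    raw = stimulus.carrier * new_env
    rms = np.sqrt(np.mean(raw**2))
    if rms == 0:
        raise ValueError("degenerate envelope after target embedding")
    return replace(stimulus, samples=raw / rms, envelope=new_env,
                   target_onset_s=onset_s, target_freq_hz=freq_hz, target_depth=depth)


def envelope_psd(env: np.ndarray, fs: float, resolution_hz: float = 0.1,
                 fmax: float = 30.0):
    """Welch PSD of an envelope on the 0.1 Hz grid over (0, 30] Hz.

    The envelope is decimated to 250 Hz first (anti-aliased); short
    envelopes are mirror-padded so trial-length snippets reach the grid.
    """
    x = np.asarray(env, dtype=float)
    if fs > _ENV_ANALYSIS_RATE:
        from math import gcd
        up, down = int(round(_ENV_ANALYSIS_RATE)), int(round(fs))
        g = gcd(up, down)
        x = sps.resample_poly(x, up // g, down // g, padtype="line")
        fs = _ENV_ANALYSIS_RATE
    mirror = x.size / fs < 1.0 / resolution_hz
    # 4 s averaging windows (zero-padded to the 0.1 Hz grid) trade leakage
    # for segment averaging; long modulators then average ~14 segments
    psd = welch_psd(x - x.mean(), fs, resolution_hz, mirror_pad=mirror, window_s=4.0)
    return psd.restrict(resolution_hz / 2, fmax)


def stim_am_exponent(stimulus: Stimulus, settings=None) -> SpectralFit:
    """Trial-wise AM spectral exponent of a stimulus.

    The envelope's Welch spectrum (1-30 Hz, 0.1 Hz grid) is parameterized
    over 1-25 Hz with the stimulus settings preset (peak widths 0.5-12 Hz,
    unbounded peak count, min height 0, threshold 2.0).
    """
    env = stimulus.envelope
    if env is None:
        if stimulus.modality == "visual":
            env = stimulus.samples
        else:
            raise ValueError("stimulus carries no envelope")
    settings = settings or PRESETS["stimulus"]
    psd = envelope_psd(env, stimulus.sample_rate_hz)
    return parameterize(psd, settings)


def fit_envelope_exponent(envelope: Envelope, settings=None) -> SpectralFit:
    """AM exponent of a bare envelope (same path as stim_am_exponent)."""
    settings = settings or PRESETS["stimulus"]
    psd = envelope_psd(envelope.samples, envelope.sample_rate_hz)
    return parameterize(psd, settings)
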