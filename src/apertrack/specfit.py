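"""Welch spectral estimation and parameterization of power spectra.

A power spectrum is decomposed into an aperiodic component,

    log10 P(f) = offset - chi * log10 f,

plus a sum of Gaussian oscillatory peaks in log10-power space.  The
exponent chi is the magnitude of the 1/f slope (P ∝ f^-chi); the peaks
capture narrow-band oscillations such as the 8-12 Hz alpha rhythm.  The
fitting procedure mirrors the fixed-mode spectral-parameterization
algorithm widely used for electrophysiological spectra: an initial
robust aperiodic fit, iterative peak extraction from the flattened
spectrum, a joint bounded Gaussian refit, and a final aperiodic refit on
the peak-subtracted spectrum.

Welch estimation supports mirror padding: time-reversed copies of the
signal are appended at both ends before segmentation, tripling the
analysis length without adding information — useful for short epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal

__all__ = [
    "PowerSpectrum",
    "FitSettings",
    "PeakParams",
    "SpectralFit",
    "PRESETS",
    "welch_psd",
    "fit_aperiodic",
    "parameterize",
    "alpha_power",
    "qc_filter",
    "extract_analysis_window",
]

# cap standing in for "max number of peaks: infinite"
_HARD_PEAK_CAP = 16
# percentile of the clipped flattened spectrum used by the robust aperiodic refit
_AP_PERCENTILE = 2.5
# peaks whose center lies within this many SDs of a fit-range edge are dropped
_EDGE_SD = 1.0


@dataclass(frozen=True)
class PowerSpectrum:
    """Frequency-power pairs on a uniform grid (linear power units)."""

    freqs: np.ndarray
    power: np.ndarray
    resolution_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if freqs.size >= 2:
            steps = np.diff(freqs)
            if np.any(steps <= 0):
                raise ValueError("freqs must be strictly increasing")
            if not np.allclose(steps, self.resolution_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("freq spacing does not match resolution_hz")
        if not np.all(np.isfinite(power)):
            raise ValueError("power must be finite")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)

    def restrict(self, fmin: float, fmax: float) -> "PowerSpectrum":
        """Return the sub-spectrum with fmin <= f <= fmax (0 Hz always excluded)."""
        mask = (self.freqs >= max(fmin, self.resolution_hz * 1e-9)) & (self.freqs <= fmax)
        mask &= self.freqs > 0
        return PowerSpectrum(self.freqs[mask], self.power[mask], self.resolution_hz, self.meta)


@dataclass(frozen=True)
class FitSettings:
    """Settings of the spectral parameterization.

    peak_width_limits are full-width bounds in Hz; internally Gaussian SDs
    are bounded by half these values.  min_peak_height is in log10-power
    units above the aperiodic component; peak_threshold is in multiples of
    the SD of the flattened spectrum.  max_n_peaks may be ``None``
    ("infinite"), implemented as a hard cap with a warning.
    """

    peak_width_limits: tuple = (1.0, 8.0)
    max_n_peaks: int | None = 8
    min_peak_height: float = 0.05
    peak_threshold: float = 2.0
    fit_range: tuple = (3.0, 55.0)
    aperiodic_mode: str = "fixed"

    def __post_init__(self):
        lo, hi = self.peak_width_limits
        if not (0 < lo < hi):
            raise ValueError("peak_width_limits must be positive and ordered")
        if self.fit_range[0] >= self.fit_range[1]:
            raise ValueError("fit_range must be ordered")
        if self.aperiodic_mode != "fixed":
            raise ValueError("only the 'fixed' aperiodic mode is supported")

    @property
    def effective_max_peaks(self) -> int:
        if self.max_n_peaks is None:
            return _HARD_PEAK_CAP
        return int(self.max_n_peaks)


#: Named setting presets: anaesthesia EEG epochs, task-EEG trials, stimulus envelopes.
PRESETS = {
    "anaesthesia": FitSettings((1.0, 8.0), 8, 0.05, 2.0, (3.0, 55.0)),
    "eeg_trial": FitSettings((1.0, 8.0), 8, 0.05, 2.0, (3.0, 55.0)),
    "stimulus": FitSettings((0.5, 12.0), None, 0.0, 2.0, (1.0, 25.0)),
}


@dataclass(frozen=True)
class PeakParams:
    center_hz: float
    height: float  # log10-power above the aperiodic component
    width_hz: float  # Gaussian SD


@dataclass(frozen=True)
class SpectralFit:
    offset: float
    exponent: float
    peaks: tuple
    r_squared: float
    fit_error: float  # mean absolute log10 residual
    settings: FitSettings
    freqs: np.ndarray | None = None
    converged: bool = True

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Evaluate the full model (log10 power) on `freqs`."""
        freqs = np.asarray(freqs, dtype=float)
        out = self.offset - self.exponent * np.log10(freqs)
        for pk in self.peaks:
            out = out + pk.height * np.exp(-((freqs - pk.center_hz) ** 2) / (2 * pk.width_hz**2))
        return out


def welch_psd(signal_in, sample_rate_hz: float, resolution_hz: float,
              mirror_pad: bool = False, window_s: float | None = None) -> PowerSpectrum:
    """Hann-windowed averaged periodogram at the requested frequency resolution.

    With ``mirror_pad`` the time-reversed signal is prepended and appended,
    tripling the analysis length.  The averaging window defaults to
    1/resolution seconds; a shorter ``window_s`` trades grid-independent
    resolution for more segment averaging, with the FFT length zero-padded
    to keep the requested grid (MATLAB ``pwelch`` semantics).  Signals
    shorter than one window are likewise zero-padded, as long as the
    padded duration is at least 1/resolution.
    """
    x = np.asarray(signal_in, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if mirror_pad:
        x = np.concatenate([x[::-1], x, x[::-1]])
    nfft = int(round(sample_rate_hz / resolution_hz))
    if nfft < 2:
        raise ValueError("resolution too coarse for the sample rate")
    if x.size / sample_rate_hz < 1.0 / resolution_hz:
        # zero-padding may refine the grid, but not below 1/duration of (padded) data
        raise ValueError(
            "requested resolution is finer than 1/duration of the (padded) signal"
        )
    nperseg = min(x.size, nfft)
    if window_s is not None:
        nperseg = min(nperseg, max(2, int(round(window_s * sample_rate_hz))))
    freqs, power = signal.welch(
        x, fs=sample_rate_hz, window="hann", nperseg=nperseg, nfft=nfft,
        noverlap=nperseg // 2, detrend="constant", scaling="density",
    )
    meta = {
        "window": "hann", "nperseg": int(nperseg), "nfft": int(nfft),
        "overlap": 0.5, "mirror_pad": bool(mirror_pad),
        "analysis_length": int(x.size),
    }
    return PowerSpectrum(freqs, power, resolution_hz, meta)


def _aperiodic_model(log_f, offset, exponent):
    return offset - exponent * log_f


def _simple_ap_fit(log_f, log_p):
    A = np.column_stack([np.ones_like(log_f), -log_f])
    coef, *_ = np.linalg.lstsq(A, log_p, rcond=None)
    return float(coef[0]), float(coef[1])


def _robust_ap_fit(log_f, log_p):
    """Aperiodic fit that discounts points lying above the bulk (peaks).

    Initial least squares, then a refit using only the points whose
    positive residual falls at or below the 2.5th percentile of the
    clipped flattened spectrum.
    """
    off0, exp0 = _simple_ap_fit(log_f, log_p)
    flat = log_p - _aperiodic_model(log_f, off0, exp0)
    flat = np.clip(flat, 0, None)
    thresh = np.percentile(flat, _AP_PERCENTILE)
    mask = flat <= thresh
    if mask.sum() < 3:
        return off0, exp0
    A = np.column_stack([np.ones(mask.sum()), -log_f[mask]])
    coef, *_ = np.linalg.lstsq(A, log_p[mask], rcond=None)
    return float(coef[0]), float(coef[1])


def fit_aperiodic(psd: PowerSpectrum, settings: FitSettings) -> tuple:
    """Robust aperiodic fit; returns (offset, exponent)."""
    sub = psd.restrict(*settings.fit_range)
    if sub.freqs.size < 3:
        raise ValueError("fewer than 3 points in the fit range")
    if np.any(sub.power <= 0):
        raise ValueError("power must be positive within the fit range")
    return _robust_ap_fit(np.log10(sub.freqs), np.log10(sub.power))


def _gaussian(freqs, center, height, sd):
    return height * np.exp(-((freqs - center) ** 2) / (2 * sd**2))


def _multi_gaussian(freqs, params):
    out = np.zeros_like(freqs)
    for c, h, s in params.reshape(-1, 3):
        out += _gaussian(freqs, c, h, s)
    return out


def _guess_peaks(freqs, flat, settings: FitSettings):
    """Iteratively extract Gaussian guesses from the flattened spectrum."""
    flat = flat.copy()
    lo_sd = settings.peak_width_limits[0] / 2
    hi_sd = settings.peak_width_limits[1] / 2
    guesses = []
    max_peaks = settings.effective_max_peaks
    if settings.max_n_peaks is None and max_peaks == _HARD_PEAK_CAP:
        cap_warn = True
    else:
        cap_warn = False
    while len(guesses) < max_peaks:
        idx = int(np.argmax(flat))
        height = flat[idx]
        if height <= settings.min_peak_height or height <= settings.peak_threshold * np.std(flat):
            break
        center = freqs[idx]
        # width from the half-height span around the maximum
        half = height / 2
        le = idx
        while le > 0 and flat[le] > half:
            le -= 1
        ri = idx
        while ri < flat.size - 1 and flat[ri] > half:
            ri += 1
        fwhm = freqs[ri] - freqs[le]
        sd = np.clip(fwhm / (2 * np.sqrt(2 * np.log(2))), lo_sd, hi_sd)
        # drop peaks overlapping the fit-range edges
        if center - _EDGE_SD * sd < freqs[0] or center + _EDGE_SD * sd > freqs[-1]:
            flat -= _gaussian(freqs, center, height, sd)
            np.clip(flat, None, None, out=flat)
            continue
        guesses.append((center, height, sd))
        flat -= _gaussian(freqs, center, height, sd)
    else:
        if cap_warn:
            warnings.warn(
                f"peak extraction stopped at the hard cap of {_HARD_PEAK_CAP} peaks",
                RuntimeWarning,
            )
    return guesses


def _refit_gaussians(freqs, flat, guesses, settings: FitSettings):
    """Joint bounded nonlinear least-squares refit of all Gaussian guesses."""
    lo_sd = settings.peak_width_limits[0] / 2
    hi_sd = settings.peak_width_limits[1] / 2
    p0, lower, upper = [], [], []
    for c, h, s in guesses:
        p0 += [c, h, s]
        lower += [max(freqs[0], c - 2 * s), 0.0, lo_sd]
        upper += [min(freqs[-1], c + 2 * s), np.inf, hi_sd]
    p0 = np.clip(np.asarray(p0, dtype=float), np.asarray(lower), np.asarray(upper))

    def resid(params):
        return _multi_gaussian(freqs, params) - flat

    sol = optimize.least_squares(
        resid, p0, bounds=(np.asarray(lower), np.asarray(upper)),
        xtol=1e-8, ftol=1e-8, gtol=1e-8,
    )
    return sol.x.reshape(-1, 3), sol.success


def parameterize(psd: PowerSpectrum, settings: FitSettings) -> SpectralFit:
    """Decompose a power spectrum into aperiodic + Gaussian-peak components.

    Steps: robust initial aperiodic fit; iterative peak extraction from the
    flattened spectrum (a candidate must exceed both the SD-relative
    threshold and the absolute minimum height); joint bounded Gaussian
    refit; final aperiodic refit on the peak-subtracted spectrum; goodness
    of fit (R^2 and mean absolute error) evaluated in log10 space.
    """
    sub = psd.restrict(*settings.fit_range)
    if sub.freqs.size < 3:
        raise ValueError("fewer than 3 points in the fit range")
    if np.any(sub.power <= 0):
        raise ValueError("power must be strictly positive")
    freqs = sub.freqs
    log_p = np.log10(sub.power)
    log_f = np.log10(freqs)

    try:
        off0, exp0 = _robust_ap_fit(log_f, log_p)
        flat = log_p - _aperiodic_model(log_f, off0, exp0)
        guesses = _guess_peaks(freqs, flat, settings)
        if guesses:
            params, ok = _refit_gaussians(freqs, flat, guesses, settings)
            if not ok:
                raise RuntimeError("gaussian refit did not converge")
            peak_model = _multi_gaussian(freqs, params)
        else:
            params = np.empty((0, 3))
            peak_model = np.zeros_like(freqs)
        off, exp_ = _robust_ap_fit(log_f, log_p - peak_model)
    except (RuntimeError, np.linalg.LinAlgError):
        return SpectralFit(np.nan, np.nan, (), 0.0, np.inf, settings, freqs, converged=False)

    peaks = tuple(
        PeakParams(float(c), float(h), float(s))
        for c, h, s in params
        if h > 0 and freqs[0] <= c <= freqs[-1]
    )
    model = _aperiodic_model(log_f, off, exp_) + _multi_gaussian(
        freqs, np.asarray([[p.center_hz, p.height, p.width_hz] for p in peaks]).ravel()
        if peaks else np.empty(0)
    )
    resid = log_p - model
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
    return SpectralFit(off, exp_, peaks, r2, float(np.mean(np.abs(resid))), settings, freqs)


def alpha_power(fit: SpectralFit, psd: PowerSpectrum,
                band: tuple = (8.0, 12.0)) -> float:
    """Alpha-band power estimate in log10-power units.

    If the fit detected one or more peaks with center inside the band, the
    tallest one's height is returned; otherwise the mean log10 power over
    the band serves as a substitute.
    """
    in_band = [p for p in fit.peaks if band[0] <= p.center_hz <= band[1]]
    if in_band:
        return max(p.height for p in in_band)
    sub = psd.restrict(*band)
    if sub.freqs.size == 0:
        raise ValueError("spectrum does not cover the alpha band")
    return float(np.mean(np.log10(sub.power)))


def qc_filter(fits, r2_min: float = 0.2, log=None) -> np.ndarray:
    """Boolean keep-mask: True where the fit explains >= r2_min of variance."""
    mask = np.array([f.r_squared >= r2_min for f in fits], dtype=bool)
    if log is not None and mask.size:
        log(f"qc_filter: excluded {np.mean(~mask):.1%} of {mask.size} fits")
    return mask


def extract_analysis_window(trial_signal, sample_rate_hz: float, trial_meta: dict,
                            mode: str = "trial", min_duration_s: float = 0.4):
    """Cut the spectral-analysis window out of a trial.

    In ``trial`` mode the window runs from 600 ms after stimulus onset to
    target onset (trial end when no target); trials whose target appears
    within 500 ms of trial start are excluded.  In ``rest`` mode the
    500 ms before the attention cue serves as a resting-state proxy.

    Returns ``(signal, None)`` or ``(None, reason)`` when excluded.
    """
    x = np.asarray(trial_signal, dtype=float)
    fs = float(sample_rate_hz)
    onset = float(trial_meta.get("onset_s", 0.0))
    target = trial_meta.get("target_onset_s", None)
    if mode == "rest":
        cue = float(trial_meta.get("cue_s", onset))
        start, stop = cue - 0.5, cue
    else:
        if target is not None and float(target) - onset < 0.5:
            return None, "target within 500 ms of trial start"
        start = onset + 0.6
        stop = float(target) if target is not None else x.size / fs
    i0, i1 = int(round(start * fs)), int(round(stop * fs))
    i0, i1 = max(i0, 0), min(i1, x.size)
    if (i1 - i0) / fs < min_duration_s:
        return None, "analysis window shorter than the minimum analyzable length"
    return x[i0:i1], None
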