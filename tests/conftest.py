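import numpy as np
import pandas as pd
import pytest

from apertrack.specfit import PowerSpectrum
from apertrack.synthexp import EEGGenParams, simulate_experiment


def make_powerlaw_psd(exponent, offset=1.0, peaks=(), fmin=0.5, fmax=60.0,
                      resolution=0.25, log_noise_sd=0.0, seed=0):
    """Analytic power-law spectrum (exact periodogram, optional log-space noise)."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(resolution, fmax + resolution / 2, resolution)
    freqs = freqs[freqs >= fmin]
    logp = offset - exponent * np.log10(freqs)
    for c, h, s in peaks:
        logp = logp + h * np.exp(-((freqs - c) ** 2) / (2 * s**2))
    if log_noise_sd:
        logp = logp + rng.normal(0, log_noise_sd, freqs.size)
    return PowerSpectrum(freqs, 10.0**logp, resolution)


def synthetic_trials(n_trials=432, b_aud=0.0, b_vis=0.0, noise_sd=0.1,
                     seed=0, subject=0):
    """Minimal trial frame for tracking-beta tests, built directly (no staircase)."""
    rng = np.random.default_rng(seed)
    chi_aud = rng.uniform(0, 3, n_trials)
    chi_vis = rng.uniform(0, 3, n_trials)
    sd = np.sqrt(9 / 12)
    eps_sd = np.sqrt(max(0.0, 1 - b_aud**2 - b_vis**2))
    att = np.where(np.repeat(np.arange(n_trials // 36), 36) % 2 == 0,
                   "auditory", "visual")[:n_trials]
    exp = 1.5 + noise_sd * (b_aud * (chi_aud - 1.5) / sd
                            + b_vis * (chi_vis - 1.5) / sd
                            + eps_sd * rng.normal(0, 1, n_trials))
    return pd.DataFrame({
        "subject": subject, "block": np.repeat(np.arange(n_trials // 36 + 1), 36)[:n_trials],
        "trial": np.arange(n_trials), "attention": att,
        "chi_aud": chi_aud, "chi_vis": chi_vis,
        "depth": 0.3, "correct": rng.integers(0, 2, n_trials),
        "rt_s": rng.uniform(0.3, 1.0, n_trials),
        "exp_Cz": exp,
    })


@pytest.fixture(scope="session")
def coupled_experiment():
    """Six-subject fast-tier experiment with planted couplings 0.3/0.3."""
    gen = EEGGenParams(b_aud=0.3, b_vis=0.3, noise_sd=0.1)
    return simulate_experiment(n_subjects=6, gen=gen, seed=11)
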