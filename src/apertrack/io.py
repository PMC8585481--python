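"""Serialization: trial tables, spectra, fits, kernels, audio, provenance.

Canonical formats: TSV (tab-separated, UTF-8, '.' decimal) for tables and
time series, RIFF WAVE for auditory stimuli, JSON for records and
provenance.  Every stochastic pipeline stage derives its seed
deterministically from a master seed plus the stage name, and every CLI
run writes a provenance JSON recording config, seeds and versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .specfit import FitSettings, PeakParams, PowerSpectrum, SpectralFit
from .synthexp import TRFKernel

__all__ = [
    "derive_seed", "read_trialtable", "write_trialtable",
    "write_psd", "read_psd", "write_fit", "read_fit",
    "write_kernel", "read_kernel", "write_wav", "write_envelope_tsv",
    "write_provenance",
]

REQUIRED_TRIAL_COLUMNS = {
    "subject": "int64", "block": "int64", "trial": "int64",
    "attention": "object", "chi_aud": "float64", "chi_vis": "float64",
    "depth": "float64", "correct": "int64", "rt_s": "float64",
}
_ATTENTION_VALUES = {"auditory", "visual"}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from a master seed + name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def write_trialtable(table: pd.DataFrame, path) -> None:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing required column(s): {missing}")
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_trialtable(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing required column(s): {missing}")
    bad = set(df["attention"].unique()) - _ATTENTION_VALUES
    if bad:
        raise ValueError(f"invalid attention value(s): {sorted(bad)}")
    for col, dtype in REQUIRED_TRIAL_COLUMNS.items():
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"column '{col}' is not of type {dtype}: {exc}") from exc
    if (df["depth"] < 0).any() or (df["depth"] > 1).any():
        raise ValueError("column 'depth' must lie in [0, 1]")
    if not set(df["correct"].unique()) <= {0, 1}:
        raise ValueError("column 'correct' must be 0/1")
    return df


def write_psd(psd: PowerSpectrum, path) -> None:
    pd.DataFrame({"freq_hz": psd.freqs, "power": psd.power}).to_csv(
        path, sep="\t", index=False)


def read_psd(path, resolution_hz: float | None = None) -> PowerSpectrum:
    df = pd.read_csv(path, sep="\t")
    for col in ("freq_hz", "power"):
        if col not in df.columns:
            raise ValueError(f"PSD file is missing column '{col}'")
    freqs = df["freq_hz"].to_numpy(float)
    if resolution_hz is None:
        resolution_hz = float(np.median(np.diff(freqs)))
    return PowerSpectrum(freqs, df["power"].to_numpy(float), resolution_hz)


def _settings_dict(s: FitSettings) -> dict:
    d = dataclasses.asdict(s)
    d["peak_width_limits"] = list(s.peak_width_limits)
    d["fit_range"] = list(s.fit_range)
    return d


def write_fit(fit: SpectralFit, path, seed: int | None = None) -> None:
    rec = {
        "offset": fit.offset, "exponent": fit.exponent,
        "peaks": [dataclasses.asdict(p) for p in fit.peaks],
        "r_squared": fit.r_squared, "fit_error": fit.fit_error,
        "converged": fit.converged, "settings": _settings_dict(fit.settings),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(rec, indent=1))


def read_fit(path) -> SpectralFit:
    rec = json.loads(Path(path).read_text())
    st = rec["settings"]
    settings = FitSettings(tuple(st["peak_width_limits"]), st["max_n_peaks"],
                           st["min_peak_height"], st["peak_threshold"],
                           tuple(st["fit_range"]), st["aperiodic_mode"])
    peaks = tuple(PeakParams(**p) for p in rec["peaks"])
    return SpectralFit(rec["offset"], rec["exponent"], peaks, rec["r_squared"],
                       rec["fit_error"], settings, converged=rec["converged"])


def write_kernel(kernel: TRFKernel, path_tsv, path_json=None) -> None:
    pd.DataFrame({"lag_s": kernel.lags_s, "weight": kernel.weights}).to_csv(
        path_tsv, sep="\t", index=False)
    if path_json is not None:
        Path(path_json).write_text(json.dumps({
            "ridge_lambda": kernel.ridge_lambda, "intercept": kernel.intercept,
            "modality": kernel.modality, "attention": kernel.attention,
        }, indent=1))


def read_kernel(path_tsv, path_json=None) -> TRFKernel:
    df = pd.read_csv(path_tsv, sep="\t")
    meta = json.loads(Path(path_json).read_text()) if path_json else {}
    return TRFKernel(df["lag_s"].to_numpy(), df["weight"].to_numpy(),
                     meta.get("ridge_lambda", 0.0), meta.get("intercept", 0.0),
                     meta.get("modality"), meta.get("attention"))


def write_wav(samples: np.ndarray, sample_rate_hz: float, path,
              dtype: str = "float32") -> None:
    """RIFF WAVE export (PCM16 or float32) via scipy.io.wavfile."""
    from scipy.io import wavfile

    x = np.asarray(samples, float)
    if dtype == "pcm16":
        peak = np.max(np.abs(x)) or 1.0
        data = np.round(x / peak * 32767).astype(np.int16)
    elif dtype == "float32":
        data = x.astype(np.float32)
    else:
        raise ValueError("dtype must be 'pcm16' or 'float32'")
    wavfile.write(path, int(round(sample_rate_hz)), data)


def write_envelope_tsv(samples: np.ndarray, sample_rate_hz: float, path) -> None:
    t = np.arange(len(samples)) / sample_rate_hz
    pd.DataFrame({"time_s": t, "value": samples}).to_csv(path, sep="\t", index=False)


def write_provenance(path, config: dict, master_seed: int, stage_seeds: dict) -> None:
    rec = {
        "config": config,
        "master_seed": master_seed,
        "stage_seeds": stage_seeds,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    try:
        from importlib.metadata import version
        rec["versions"]["apertrack"] = version("apertrack")
    except Exception:
        pass
    Path(path).write_text(json.dumps(rec, indent=1, default=str))
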