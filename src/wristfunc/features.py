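"""The 49 window-level time- and frequency-domain features.

Per channel (vector magnitude VM plus the three axes) the time-domain block
holds mean, sample SD, coefficient of variation, min, max, 25%/75% quantiles,
third and fourth central moments, skewness and kurtosis (11 statistics x 4
channels = 44 features).  Two angle features summarize wrist orientation and
three spectral features summarize the VM spectrum: p625 (fraction of power in
the 0.6-2.5 Hz human-movement band), df (dominant frequency) and fpdf
(modulus at df over the sum of moduli).

Conventions, chosen once and tested against independent oracles:

* SD uses the n-1 denominator; third/fourth moments are population *central*
  moments; skewness = m3 / m2**1.5; kurtosis = m4 / m2**2 (non-excess,
  Gaussian -> 3).  Zero-variance windows yield skewness = kurtosis = 0.
* cv = 100 * SD / mean, 0 with a warning when |mean| < 1e-12 g.
* Quantiles interpolate linearly between order statistics.
* angle_i = asin(clip(x_i / vm_i, -1, 1)) in radians; vm_i = 0 -> angle 0.
* Spectral features use an untapered DFT of the mean-removed VM series over
  strictly positive frequencies (the DC bin is excluded so the gravity offset
  cannot dominate).  p625 uses squared moduli; fpdf uses raw moduli.  Ties
  for the dominant frequency break toward the lowest frequency.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .signals import SignalWindow

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "MOVEMENT_BAND_HZ",
    "vector_magnitude",
    "time_domain_features",
    "angle_features",
    "spectral_features",
    "extract_features",
    "feature_table",
]

MOVEMENT_BAND_HZ = (0.6, 2.5)  # human-movement frequency band, inclusive
_MEAN_GUARD = 1e-12

_CHANNELS = ("vm", "x", "y", "z")

_TIME_NAMES: tuple[str, ...] = (
    "mvm", "mean_x", "mean_y", "mean_z",
    "sdvm", "sd_x", "sd_y", "sd_z",
    "cv_vm", "cv_x", "cv_y", "cv_z",
    "min_vm", "min_x", "min_y", "min_z",
    "max_vm", "max_x", "max_y", "max_z",
    "lower_vm_25", "lower_x_25", "lower_y_25", "lower_z_25",
    "upper_vm_75", "upper_x_75", "upper_y_75", "upper_z_75",
    "third_vm", "third_x", "third_y", "third_z",
    "fourth_vm", "fourth_x", "fourth_y", "fourth_z",
    "skewness_vm", "skewness_x", "skewness_y", "skewness_z",
    "kurtosis_vm", "kurtosis_x", "kurtosis_y", "kurtosis_z",
)

#: The 49 feature names in canonical emission order.
FEATURE_NAMES: tuple[str, ...] = _TIME_NAMES + (
    "mangle", "sdangle", "p625", "df", "fpdf",
)

assert len(FEATURE_NAMES) == 49


def vector_magnitude(window: SignalWindow | np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes."""
    samples = window.samples if isinstance(window, SignalWindow) else window
    return np.sqrt(np.sum(np.square(np.asarray(samples, dtype=float)), axis=1))


def _channel_stats(values: np.ndarray, name: str) -> dict[str, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if abs(mean) < _MEAN_GUARD:
        logger.warning("near-zero mean on channel %s; cv set to 0", name)
        cv = 0.0
    else:
        cv = 100.0 * sd / mean
    centered = values - mean
    m2 = float(np.mean(centered**2))
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    if m2 > 0:
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    else:
        skew = 0.0
        kurt = 0.0
    q25, q75 = np.quantile(values, [0.25, 0.75])
    return {
        "mean": mean,
        "sd": sd,
        "cv": cv,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "q25": float(q25),
        "q75": float(q75),
        "third": m3,
        "fourth": m4,
        "skewness": skew,
        "kurtosis": kurt,
    }


def time_domain_features(window: SignalWindow) -> dict[str, float]:
    """The 44 per-channel statistics over VM, x, y and z."""
    if window.samples.shape[0] < 2:
        raise ValueError("window must contain at least two samples")
    vm = vector_magnitude(window)
    stats = {
        "vm": _channel_stats(vm, "vm"),
        "x": _channel_stats(window.x, "x"),
        "y": _channel_stats(window.y, "y"),
        "z": _channel_stats(window.z, "z"),
    }
    out: dict[str, float] = {}
    out["mvm"] = stats["vm"]["mean"]
    out["sdvm"] = stats["vm"]["sd"]
    out["cv_vm"] = stats["vm"]["cv"]
    out["min_vm"] = stats["vm"]["min"]
    out["max_vm"] = stats["vm"]["max"]
    out["lower_vm_25"] = stats["vm"]["q25"]
    out["upper_vm_75"] = stats["vm"]["q75"]
    out["third_vm"] = stats["vm"]["third"]
    out["fourth_vm"] = stats["vm"]["fourth"]
    out["skewness_vm"] = stats["vm"]["skewness"]
    out["kurtosis_vm"] = stats["vm"]["kurtosis"]
    for axis in ("x", "y", "z"):
        s = stats[axis]
        out[f"mean_{axis}"] = s["mean"]
        out[f"sd_{axis}"] = s["sd"]
        out[f"cv_{axis}"] = s["cv"]
        out[f"min_{axis}"] = s["min"]
        out[f"max_{axis}"] = s["max"]
        out[f"lower_{axis}_25"] = s["q25"]
        out[f"upper_{axis}_75"] = s["q75"]
        out[f"third_{axis}"] = s["third"]
        out[f"fourth_{axis}"] = s["fourth"]
        out[f"skewness_{axis}"] = s["skewness"]
        out[f"kurtosis_{axis}"] = s["kurtosis"]
    return {name: out[name] for name in _TIME_NAMES}


def angle_features(
    window: SignalWindow, degrees: bool = False
) -> tuple[float, float]:
    """Mean and sample SD of the x-axis/VM inclination angle."""
    vm = vector_magnitude(window)
    x = window.x
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vm > 0, x / np.where(vm > 0, vm, 1.0), 0.0)
    if np.any(vm == 0):
        logger.warning(
            "%d zero-magnitude samples; angle set to 0", int((vm == 0).sum())
        )
    angles = np.arcsin(np.clip(ratio, -1.0, 1.0))
    if degrees:
        angles = np.degrees(angles)
    return float(np.mean(angles)), float(np.std(angles, ddof=1))


def spectral_features(window: SignalWindow) -> tuple[float, float, float]:
    """(p625, df, fpdf) from the mean-removed VM spectrum, DC excluded."""
    vm = vector_magnitude(window)
    if vm.size < 2:
        raise ValueError("window must contain at least two samples")
    rate = window.sampling_rate_hz
    spectrum = np.fft.rfft(vm - np.mean(vm))
    freqs = np.fft.rfftfreq(vm.size, d=1.0 / rate)
    positive = freqs > 0
    freqs = freqs[positive]
    moduli = np.abs(spectrum[positive])
    power = moduli**2
    total_power = float(power.sum())
    total_moduli = float(moduli.sum())
    if total_power <= 0 or not np.isfinite(total_power):
        logger.warning("zero VM spectrum; spectral features degenerate")
        return 0.0, float(freqs[0]), 0.0
    lo, hi = MOVEMENT_BAND_HZ
    in_band = (freqs >= lo) & (freqs <= hi)
    p625 = float(power[in_band].sum() / total_power)
    # ties (within float noise) break toward the lowest frequency
    peak_modulus = float(moduli.max())
    peak = int(np.flatnonzero(moduli >= peak_modulus * (1 - 1e-9))[0])
    df = float(freqs[peak])
    fpdf = float(moduli[peak] / total_moduli)
    return p625, df, fpdf


def extract_features(window: SignalWindow) -> dict[str, float]:
    """Assemble the full 49-name feature vector for one window."""
    values = time_domain_features(window)
    mangle, sdangle = angle_features(window)
    p625, df, fpdf = spectral_features(window)
    values.update(
        {"mangle": mangle, "sdangle": sdangle,
         "p625": p625, "df": df, "fpdf": fpdf}
    )
    vector = {name: values[name] for name in FEATURE_NAMES}
    if len(vector) != 49:
        raise AssertionError("feature vector must contain exactly 49 values")
    return vector


def feature_table(
    windows: list[SignalWindow],
    labels: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """One row per window: identifiers, the 49 features, optional labels.

    ``labels`` maps canonical activity names to (type, intensity) pairs; when
    omitted the packaged catalog is used.
    """
    from . import taxonomy

    rows = []
    for window in windows:
        row: dict[str, object] = {
            "subject_id": window.subject_id,
            "activity_name": window.activity_name,
            "window_index": window.window_index,
        }
        row.update(extract_features(window))
        if labels is not None:
            type_cat, intensity_cat = labels[window.activity_name]
        else:
            type_cat, intensity_cat = taxonomy.map_activity(
                window.activity_name
            )
        row["type_category"] = type_cat
        row["intensity_category"] = intensity_cat
        rows.append(row)
    return pd.DataFrame(rows)
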