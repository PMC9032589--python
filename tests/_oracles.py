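"""Independent naive-formula oracles used to cross-check the package.

Everything here is deliberately written with explicit loops and direct
formulas, sharing no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_vm(samples: np.ndarray) -> np.ndarray:
    out = []
    for x, y, z in samples:
        out.append(math.sqrt(x * x + y * y + z * z))
    return np.array(out)


def oracle_mean(v) -> float:
    return sum(v) / len(v)


def oracle_sd(v) -> float:
    m = oracle_mean(v)
    return math.sqrt(sum((a - m) ** 2 for a in v) / (len(v) - 1))


def oracle_cv(v) -> float:
    m = oracle_mean(v)
    if abs(m) < 1e-12:
        return 0.0
    return 100.0 * oracle_sd(v) / m


def oracle_quantile(v, q: float) -> float:
    """Linear interpolation between order statistics (type-7)."""
    s = sorted(v)
    pos = q * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def oracle_central_moment(v, k: int) -> float:
    m = oracle_mean(v)
    return sum((a - m) ** k for a in v) / len(v)


def oracle_skewness(v) -> float:
    m2 = oracle_central_moment(v, 2)
    if m2 == 0:
        return 0.0
    return oracle_central_moment(v, 3) / m2**1.5


def oracle_kurtosis(v) -> float:
    m2 = oracle_central_moment(v, 2)
    if m2 == 0:
        return 0.0
    return oracle_central_moment(v, 4) / m2**2


def oracle_channel(values) -> dict[str, float]:
    return {
        "mean": oracle_mean(values),
        "sd": oracle_sd(values),
        "cv": oracle_cv(values),
        "min": min(values),
        "max": max(values),
        "q25": oracle_quantile(values, 0.25),
        "q75": oracle_quantile(values, 0.75),
        "third": oracle_central_moment(values, 3),
        "fourth": oracle_central_moment(values, 4),
        "skewness": oracle_skewness(values),
        "kurtosis": oracle_kurtosis(values),
    }


def oracle_angles(samples: np.ndarray) -> tuple[float, float]:
    angles = []
    for x, y, z in samples:
        vm = math.sqrt(x * x + y * y + z * z)
        if vm == 0:
            angles.append(0.0)
        else:
            angles.append(math.asin(max(-1.0, min(1.0, x / vm))))
    return oracle_mean(angles), oracle_sd(angles)


def oracle_spectral(
    samples: np.ndarray, rate_hz: float
) -> tuple[float, float, float]:
    """(p625, df, fpdf) by direct DFT summation over positive frequencies."""
    vm = oracle_vm(samples)
    vm = vm - oracle_mean(vm)
    n = len(vm)
    n_pos = n // 2  # positive rfft bins, Nyquist included for even n
    freqs, moduli = [], []
    for k in range(1, n_pos + 1):
        re = sum(vm[j] * math.cos(-2 * math.pi * k * j / n) for j in range(n))
        im = sum(vm[j] * math.sin(-2 * math.pi * k * j / n) for j in range(n))
        freqs.append(k * rate_hz / n)
        moduli.append(math.hypot(re, im))
    power = [m * m for m in moduli]
    total_power = sum(power)
    if total_power <= 0:
        return 0.0, freqs[0], 0.0
    p625 = (
        sum(p for f, p in zip(freqs, power) if 0.6 <= f <= 2.5) / total_power
    )
    best = 0
    for k in range(1, len(moduli)):
        if moduli[k] > moduli[best]:
            best = k
    return p625, freqs[best], moduli[best] / sum(moduli)


def oracle_feature_vector(samples: np.ndarray, rate_hz: float) -> dict[str, float]:
    """All 49 features via the naive formulas above."""
    vm = oracle_vm(samples)
    chans = {
        "vm": oracle_channel(list(vm)),
        "x": oracle_channel(list(samples[:, 0])),
        "y": oracle_channel(list(samples[:, 1])),
        "z": oracle_channel(list(samples[:, 2])),
    }
    out: dict[str, float] = {}
    rename = {
        ("vm", "mean"): "mvm", ("vm", "sd"): "sdvm", ("vm", "cv"): "cv_vm",
        ("vm", "min"): "min_vm", ("vm", "max"): "max_vm",
        ("vm", "q25"): "lower_vm_25", ("vm", "q75"): "upper_vm_75",
        ("vm", "third"): "third_vm", ("vm", "fourth"): "fourth_vm",
        ("vm", "skewness"): "skewness_vm", ("vm", "kurtosis"): "kurtosis_vm",
    }
    for axis in ("x", "y", "z"):
        rename.update(
            {
                (axis, "mean"): f"mean_{axis}", (axis, "sd"): f"sd_{axis}",
                (axis, "cv"): f"cv_{axis}", (axis, "min"): f"min_{axis}",
                (axis, "max"): f"max_{axis}",
                (axis, "q25"): f"lower_{axis}_25",
                (axis, "q75"): f"upper_{axis}_75",
                (axis, "third"): f"third_{axis}",
                (axis, "fourth"): f"fourth_{axis}",
                (axis, "skewness"): f"skewness_{axis}",
                (axis, "kurtosis"): f"kurtosis_{axis}",
            }
        )
    for (chan, stat), name in rename.items():
        out[name] = chans[chan][stat]
    out["mangle"], out["sdangle"] = oracle_angles(samples)
    out["p625"], out["df"], out["fpdf"] = oracle_spectral(samples, rate_hz)
    return out


def oracle_smooth(timestamps, values, span_s: float):
    """Centered running mean with inclusive endpoints, by exhaustive loops."""
    out = []
    half = span_s / 2.0
    for t in timestamps:
        members = [
            v for u, v in zip(timestamps, values) if t - half <= u <= t + half
        ]
        out.append(sum(members) / len(members))
    return np.array(out)


def oracle_steady_state(
    timestamps, values, plateau_s: float, span_s: float = 30.0,
    second_half_only: bool = True,
):
    """Brute-force plateau scan mirroring the documented selection rule."""
    t = list(timestamps)
    v = list(oracle_smooth(timestamps, values, span_s))
    t_end = t[-1]
    starts = [i for i in range(len(t)) if t[i] + plateau_s <= t_end + 1e-9]
    if second_half_only:
        earliest = min(t[0] + (t_end - t[0]) / 2.0, t[starts[-1]])
        eligible = [i for i in starts if t[i] >= earliest - 1e-9]
        starts = eligible or [starts[-1]]
    best_sd, best_mean, best_interval = float("inf"), None, None
    for i in starts:
        seg = [v[j] for j in range(i, len(t)) if t[j] <= t[i] + plateau_s]
        if len(seg) < 2:
            continue
        mean = sum(seg) / len(seg)
        sd = math.sqrt(
            sum((a - mean) ** 2 for a in seg) / (len(seg) - 1)
        )
        if sd <= best_sd:
            best_sd, best_mean = sd, mean
            best_interval = (t[i], t[i] + plateau_s)
    return best_mean, best_interval
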