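"""Raw accelerometry / calorimetry I-O, 60 s windowing, steady-state METs.

Acceleration is in units of g at a nominal 100 Hz.  Oxygen uptake (VO2,
mL·min⁻¹·kg⁻¹) is breath-by-breath at irregular timestamps; it is smoothed
with a centered 30 s running average and summarized per bout as the mean over
the flattest ~2 min plateau, then divided by 3.5 to give METs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TriaxialBout",
    "SignalWindow",
    "BreathSeries",
    "SteadyStateMET",
    "read_bout",
    "read_breaths",
    "segment_windows",
    "smooth_vo2",
    "steady_state_vo2",
    "vo2_to_mets",
]

VO2_PER_MET = 3.5  # mL·min⁻¹·kg⁻¹ per MET (resting VO2 convention)


@dataclass
class TriaxialBout:
    """One subject-activity recording of tri-axial acceleration."""

    subject_id: str
    activity_name: str
    samples: np.ndarray  # shape (n, 3), units of g
    sampling_rate_hz: float = 100.0
    t0: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.samples.shape[0] < 1:
            raise ValueError("bout must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValueError("bout contains non-finite samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class SignalWindow:
    """A fixed-duration slice of a bout used for feature extraction."""

    subject_id: str
    activity_name: str
    window_index: int
    samples: np.ndarray  # shape (n, 3)
    sampling_rate_hz: float
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = round(self.duration_s * self.sampling_rate_hz)
        if self.samples.shape != (expected, 3):
            raise ValueError(
                f"window must hold exactly {expected} triples, "
                f"got shape {self.samples.shape}"
            )

    @property
    def x(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.samples[:, 2]


@dataclass
class BreathSeries:
    """Breath-by-breath VO2 at strictly increasing timestamps."""

    timestamps_s: np.ndarray
    vo2: np.ndarray  # mL·min⁻¹·kg⁻¹

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.timestamps_s.shape != self.vo2.shape:
            raise ValueError("timestamps and vo2 must have equal length")
        if self.timestamps_s.size == 0:
            raise ValueError("breath series is empty")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.vo2 < 0):
            raise ValueError("vo2 values must be non-negative")

    def __len__(self) -> int:
        return self.timestamps_s.size

    @property
    def duration_s(self) -> float:
        return float(self.timestamps_s[-1] - self.timestamps_s[0])


@dataclass(frozen=True)
class SteadyStateMET:
    """Plateau VO2 summary for one bout, expressed in METs."""

    subject_id: str
    activity_name: str
    vo2_ss: float
    mets: float
    plateau_interval_s: tuple[float, float]

    def __post_init__(self) -> None:
        if not np.isclose(self.mets, self.vo2_ss / VO2_PER_MET):
            raise ValueError("mets must equal vo2_ss / 3.5")
        if self.mets <= 0:
            raise ValueError("mets must be positive")


def read_bout(
    path: str | Path,
    subject_id: str = "",
    activity_name: str = "",
    sampling_rate_hz: float | None = None,
) -> TriaxialBout:
    """Read a bout from CSV with columns time,x,y,z (or x,y,z + declared rate).

    Rows containing NaN/inf are dropped with a logged count.  A non-monotone
    time column, missing columns, or an empty file raise ``ValueError``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if {"x", "y", "z"} - set(frame.columns):
        raise ValueError(f"{path}: requires columns x, y, z")
    time_col = next(
        (c for c in ("time", "timestamp", "time_s") if c in frame.columns),
        None,
    )
    if time_col is not None:
        t = frame[time_col].to_numpy(dtype=float)
        finite_t = np.isfinite(t)
        if np.any(np.diff(t[finite_t]) <= 0):
            raise ValueError(f"{path}: time column is not strictly increasing")
        if sampling_rate_hz is None:
            dt = np.median(np.diff(t[finite_t]))
            if dt <= 0:
                raise ValueError(f"{path}: cannot infer sampling rate")
            sampling_rate_hz = 1.0 / dt
    elif sampling_rate_hz is None:
        raise ValueError(
            f"{path}: no time column; sampling_rate_hz must be declared"
        )
    xyz = frame[["x", "y", "z"]].to_numpy(dtype=float)
    keep = np.isfinite(xyz).all(axis=1)
    if time_col is not None:
        keep &= np.isfinite(frame[time_col].to_numpy(dtype=float))
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("%s: dropped %d non-finite rows", path, dropped)
    xyz = xyz[keep]
    if xyz.shape[0] == 0:
        raise ValueError(f"{path}: no valid rows after filtering")
    return TriaxialBout(
        subject_id=subject_id,
        activity_name=activity_name,
        samples=xyz,
        sampling_rate_hz=float(sampling_rate_hz),
    )


def read_breaths(path: str | Path) -> BreathSeries:
    """Read a calorimetry CSV with columns time_s, vo2_mlkgmin."""
    frame = pd.read_csv(path)
    frame.columns = [c.strip().lower() for c in frame.columns]
    if {"time_s", "vo2_mlkgmin"} - set(frame.columns):
        raise ValueError(f"{path}: requires columns time_s, vo2_mlkgmin")
    return BreathSeries(
        frame["time_s"].to_numpy(dtype=float),
        frame["vo2_mlkgmin"].to_numpy(dtype=float),
    )


def segment_windows(
    bout: TriaxialBout,
    window_s: float = 60.0,
    gap_s: float = 0.0,
    trim_s: float = 0.0,
) -> list[SignalWindow]:
    """Tile a bout into non-overlapping fixed-duration windows.

    Windows are cut consecutively from the bout start (after an optional
    ``trim_s`` lead-in and with an optional ``gap_s`` between windows); the
    trailing partial window is dropped, never padded.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if gap_s < 0 or trim_s < 0:
        raise ValueError("gap_s and trim_s must be non-negative")
    rate = bout.sampling_rate_hz
    win_n = round(window_s * rate)
    gap_n = round(gap_s * rate)
    start = round(trim_s * rate)
    windows: list[SignalWindow] = []
    index = 0
    while start + win_n <= bout.n_samples:
        windows.append(
            SignalWindow(
                subject_id=bout.subject_id,
                activity_name=bout.activity_name,
                window_index=index,
                samples=bout.samples[start : start + win_n],
                sampling_rate_hz=rate,
                duration_s=window_s,
            )
        )
        start += win_n + gap_n
        index += 1
    return windows


def smooth_vo2(series: BreathSeries, span_s: float = 30.0) -> BreathSeries:
    """Centered running average over breaths within ±span_s/2 of each breath.

    Timestamps are unchanged; inclusive endpoints; tolerant of irregular
    breath spacing.
    """
    if span_s <= 0:
        raise ValueError("span_s must be positive")
    t = series.timestamps_s
    half = span_s / 2.0
    csum = np.concatenate(([0.0], np.cumsum(series.vo2)))
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return BreathSeries(t.copy(), smoothed)


def steady_state_vo2(
    series: BreathSeries,
    plateau_s: float = 120.0,
    smooth_span_s: float = 30.0,
    second_half_only: bool = True,
    subject_id: str = "",
    activity_name: str = "",
) -> SteadyStateMET:
    """Estimate plateau VO2 as the flattest contiguous ``plateau_s`` interval.

    The series is smoothed first; candidate intervals start at each breath and
    the one minimizing the within-interval standard deviation wins (ties go to
    the latest start).  By default candidates are restricted to the second
    half of the bout so the initial metabolic rise is excluded.  This is an
    automated surrogate for a manual plateau choice.
    """
    if series.duration_s < plateau_s:
        raise ValueError(
            f"series spans {series.duration_s:.1f} s, "
            f"shorter than plateau_s={plateau_s}"
        )
    smoothed = smooth_vo2(series, smooth_span_s)
    t = smoothed.timestamps_s
    v = smoothed.vo2
    t_end = t[-1]
    eps = 1e-9
    starts = [i for i in range(len(t)) if t[i] + plateau_s <= t_end + eps]
    if not starts:
        raise ValueError("no candidate plateau interval found")
    if second_half_only:
        midpoint = t[0] + (t_end - t[0]) / 2.0
        earliest = min(midpoint, t[starts[-1]])
        eligible = [i for i in starts if t[i] >= earliest - eps]
        # breath spacing can leave the second half without a candidate start;
        # fall back to the latest full-length interval
        starts = eligible or [starts[-1]]
    best_sd = np.inf
    best: tuple[int, int] | None = None
    for i in starts:
        j = int(np.searchsorted(t, t[i] + plateau_s, side="right"))
        seg = v[i:j]
        if seg.size < 2:
            continue
        sd = float(np.std(seg, ddof=1))
        if sd <= best_sd:  # <= so ties prefer the latest interval
            best_sd = sd
            best = (i, j)
    if best is None:
        raise ValueError("no candidate plateau interval found")
    i, j = best
    vo2_ss = float(np.mean(v[i:j]))
    return SteadyStateMET(
        subject_id=subject_id,
        activity_name=activity_name,
        vo2_ss=vo2_ss,
        mets=vo2_ss / VO2_PER_MET,
        plateau_interval_s=(float(t[i]), float(t[j - 1])),
    )


def vo2_to_mets(vo2: float) -> float:
    """Convert VO2 (mL·min⁻¹·kg⁻¹) to METs by dividing by 3.5."""
    if vo2 < 0:
        raise ValueError("vo2 must be non-negative")
    return vo2 / VO2_PER_MET
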