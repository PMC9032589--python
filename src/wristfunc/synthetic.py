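"""Synthetic cohort generator for end-to-end testing without laboratory data.

Generates subjects (SPPB scores, demographics), per-activity tri-axial wrist
accelerometry with activity-specific orientation/frequency/amplitude
signatures, and breath-by-breath calorimetry rising to a steady-state
plateau.  Group effects make the low-performance (LPP) group move slower and
more variably than the high-performance (HPP) group; the default frequency
ratio 0.79/1.05 is anchored to the groups' mean walk speeds.

Every signature is a design choice, not a measurement: downstream model
scores on this cohort are qualitative properties, not recovery targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import BreathSeries, TriaxialBout, segment_windows, steady_state_vo2
from .taxonomy import SubjectProfile, assign_group

logger = logging.getLogger(__name__)

__all__ = [
    "ActivitySignature",
    "GroupEffect",
    "CohortConfig",
    "BoutRecord",
    "CohortData",
    "load_signatures",
    "default_group_effects",
    "met_to_intensity",
    "met_target",
    "simulate_subject",
    "simulate_bout",
    "simulate_cohort",
    "featurize_cohort",
    "write_cohort",
]

#: LPP walk speed / HPP walk speed, the one quantitative group contrast known.
LPP_FREQ_RATIO = 0.79 / 1.05

SPPB_PARAMS = {"LPP": (7.7, 1.8, 0, 9), "HPP": (11.3, 0.8, 10, 12)}
AGE_PARAMS = {"LPP": (75.9, 6.6, 62, 89), "HPP": (70.3, 6.6, 60, 88)}
WALK_PARAMS = {"LPP": (0.79, 0.15), "HPP": (1.05, 0.17)}
BMI_PARAMS = {"LPP": (30.8, 8.8), "HPP": (27.5, 4.8)}


@dataclass(frozen=True)
class ActivitySignature:
    """Statistical fingerprint of one activity's wrist signal and energy cost."""

    activity_name: str
    gravity_axis_weights: tuple[float, float, float]
    f0_hz: float
    amp_g: float
    noise_g: float
    met_mu: float
    met_sigma: float

    def __post_init__(self) -> None:
        if self.f0_hz < 0 or self.amp_g < 0 or self.noise_g < 0:
            raise ValueError("f0_hz, amp_g, noise_g must be non-negative")
        if self.met_mu <= 0 or self.met_sigma < 0:
            raise ValueError("met_mu must be > 0 and met_sigma >= 0")
        w = np.asarray(self.gravity_axis_weights, dtype=float)
        norm = float(np.linalg.norm(w))
        if norm == 0:
            raise ValueError("gravity_axis_weights must be non-zero")
        object.__setattr__(
            self, "gravity_axis_weights", tuple((w / norm).tolist())
        )


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative/additive modifiers applied to every bout of a group."""

    freq_scale: float = 1.0
    variability_scale: float = 1.0
    met_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.freq_scale <= 0 or self.variability_scale <= 0:
            raise ValueError("scales must be positive")


def default_group_effects() -> dict[str, GroupEffect]:
    return {
        "LPP": GroupEffect(
            freq_scale=LPP_FREQ_RATIO, variability_scale=1.5, met_shift=0.0
        ),
        "HPP": GroupEffect(),
    }


@dataclass
class CohortConfig:
    n_lpp: int = 91
    n_hpp: int = 156
    seed: int = 0
    sampling_rate_hz: float = 100.0
    bout_duration_s: float = 480.0
    activities: list[str] | None = None  # None -> full catalog
    group_effects: dict[str, GroupEffect] = field(
        default_factory=default_group_effects
    )
    missing_fraction: float = 0.0
    breath_noise_sd: float = 0.3
    vo2_tau_s: float = 30.0
    # subject-level random effects: lognormal SDs on pace and amplitude,
    # plus wrist-orientation perturbation (device wear varies per person)
    f0_jitter_sd: float = 0.08
    amp_jitter_sd: float = 0.12
    orient_jitter_sd: float = 0.12

    def __post_init__(self) -> None:
        if self.n_lpp < 0 or self.n_hpp < 0 or self.n_lpp + self.n_hpp < 2:
            raise ValueError("cohort needs at least two subjects")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.bout_duration_s < 120:
            raise ValueError(
                "bout_duration_s must be >= 120 s to allow a VO2 plateau"
            )


@dataclass
class BoutRecord:
    subject_id: str
    activity_name: str
    bout: TriaxialBout
    breaths: BreathSeries
    met_target: float


@dataclass
class CohortData:
    config: CohortConfig
    subjects: list[SubjectProfile]
    bouts: list[BoutRecord]

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "sppb": [s.sppb_score for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age_years for s in self.subjects],
                "walk_speed_mps": [s.walk_speed_mps for s in self.subjects],
                "bmi": [s.bmi for s in self.subjects],
            }
        )

    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [b.subject_id for b in self.bouts],
                "activity_name": [b.activity_name for b in self.bouts],
                "met_target": [b.met_target for b in self.bouts],
            }
        )


def load_signatures(
    path: str | Path | None = None,
) -> dict[str, ActivitySignature]:
    """Load activity signatures (packaged default when *path* is None)."""
    if path is None:
        ref = resources.files("wristfunc.data") / "activity_signatures.csv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    out: dict[str, ActivitySignature] = {}
    for row in frame.itertuples():
        sig = ActivitySignature(
            activity_name=row.activity_name,
            gravity_axis_weights=(row.gx, row.gy, row.gz),
            f0_hz=row.f0_hz,
            amp_g=row.amp_g,
            noise_g=row.noise_g,
            met_mu=row.met_mu,
            met_sigma=row.met_sigma,
        )
        out[sig.activity_name] = sig
    return out


def met_to_intensity(mets: float) -> str:
    """Conventional MET cut-points; generator ground truth only."""
    if mets < 1.6:
        return "Low"
    if mets < 3.0:
        return "Light"
    return "Moderate"


def _latent_mean(target: float, sigma: float, lo: float, hi: float) -> float:
    """Latent normal mean whose range-censored mean equals *target*.

    Clipping N(mu, sigma) to [lo, hi] shifts the mean (e.g. censoring
    N(7.7, 1.8) at 9 drags the mean to ~7.46), so the latent mean is
    calibrated such that the clipped draws reproduce the published group
    means.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    def censored_mean(mu: float) -> float:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return (
            lo * norm.cdf(a)
            + hi * norm.sf(b)
            + mu * (norm.cdf(b) - norm.cdf(a))
            - sigma * (norm.pdf(b) - norm.pdf(a))
        )

    return float(brentq(lambda m: censored_mean(m) - target, lo - 3, hi + 3))


def _clipped_normal_int(
    rng: np.random.Generator, mu: float, sigma: float, lo: int, hi: int
) -> int:
    return int(np.clip(round(rng.normal(mu, sigma)), lo, hi))


def simulate_subject(
    config: CohortConfig, group: str, rng: np.random.Generator, index: int = 0
) -> SubjectProfile:
    """Draw one subject; the group label is rederived from the SPPB score."""
    mu, sigma, lo, hi = SPPB_PARAMS[group]
    sppb = _clipped_normal_int(rng, _latent_mean(mu, sigma, lo, hi), sigma, lo, hi)
    derived = assign_group(sppb)
    if derived != group:
        raise AssertionError(
            f"drawn SPPB {sppb} maps to {derived}, expected {group}"
        )
    a_mu, a_sigma, a_lo, a_hi = AGE_PARAMS[group]
    age = float(np.clip(rng.normal(a_mu, a_sigma), a_lo, a_hi))
    w_mu, w_sigma = WALK_PARAMS[group]
    walk = float(max(0.2, rng.normal(w_mu, w_sigma)))
    b_mu, b_sigma = BMI_PARAMS[group]
    bmi = float(max(15.0, rng.normal(b_mu, b_sigma)))
    return SubjectProfile(
        subject_id=f"{group}{index:03d}",
        sppb_score=sppb,
        group=derived,
        age_years=age,
        walk_speed_mps=walk,
        bmi=bmi,
    )


def met_target(
    signature: ActivitySignature,
    group_effect: GroupEffect,
    subject_z: float = 0.0,
) -> float:
    """Ground-truth steady-state METs for one bout, floored at 0.5."""
    return max(
        0.5,
        signature.met_mu
        + subject_z * signature.met_sigma
        + group_effect.met_shift,
    )


def _movement_direction(gravity: np.ndarray) -> np.ndarray:
    """Unit movement direction at ~45 deg to gravity.

    A purely gravity-orthogonal oscillation would cancel to first order in
    the vector magnitude (frequency doubling); the gravity-parallel component
    keeps the dominant VM frequency at the driving frequency.
    """
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(gravity, ref))) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(gravity, ref)
    perp /= np.linalg.norm(perp)
    m = gravity + perp
    return m / np.linalg.norm(m)


def _slow_envelope(
    n: int, rate_hz: float, rng: np.random.Generator, knot_spacing_s: float = 2.0
) -> np.ndarray:
    """Smooth unit-variance modulation, interpolated between random knots."""
    n_knots = max(2, int(np.ceil(n / rate_hz / knot_spacing_s)) + 1)
    knots = rng.standard_normal(n_knots)
    knot_t = np.linspace(0, n - 1, n_knots)
    return np.interp(np.arange(n), knot_t, knots)


def simulate_bout(
    subject_id: str,
    signature: ActivitySignature,
    group_effect: GroupEffect,
    rng: np.random.Generator,
    duration_s: float = 480.0,
    rate_hz: float = 100.0,
    met: float | None = None,
    tau_s: float = 30.0,
    breath_noise_sd: float = 0.3,
) -> tuple[TriaxialBout, BreathSeries]:
    """Simulate one bout: accelerometer trace plus breath-by-breath VO2.

    Acceleration is a static gravity component along the signature's
    orientation, a movement oscillation at ``f0_hz * freq_scale`` with a
    slowly jittered amplitude (jitter scaled by ``variability_scale``), and
    broadband Gaussian noise.  VO2 rises exponentially (time constant
    ``tau_s``) to a plateau at 3.5 x the MET target.
    """
    if duration_s < 120:
        raise ValueError("duration_s must be >= 120 s to allow a plateau")
    if met is None:
        met = met_target(signature, group_effect, rng.standard_normal())
    n = round(duration_s * rate_hz)
    t = np.arange(n) / rate_hz
    gravity = np.asarray(signature.gravity_axis_weights)
    accel = np.tile(gravity, (n, 1))
    f_move = signature.f0_hz * group_effect.freq_scale
    if f_move > 0 and signature.amp_g > 0:
        jitter = 0.2 * group_effect.variability_scale * _slow_envelope(
            n, rate_hz, rng
        )
        envelope = np.clip(signature.amp_g * (1.0 + jitter), 0.0, None)
        phase = rng.uniform(0, 2 * np.pi)
        osc = envelope * np.sin(2 * np.pi * f_move * t + phase)
        # faint second harmonic so the spectrum is not a pure line
        osc = osc + 0.25 * envelope * np.sin(
            2 * np.pi * 2 * f_move * t + rng.uniform(0, 2 * np.pi)
        )
        accel = accel + np.outer(osc, _movement_direction(gravity))
    if signature.noise_g > 0:
        accel = accel + signature.noise_g * rng.standard_normal((n, 3))
    bout = TriaxialBout(
        subject_id=subject_id,
        activity_name=signature.activity_name,
        samples=accel,
        sampling_rate_hz=rate_hz,
    )
    n_breaths_max = int(duration_s / 2.0) + 8
    gaps = rng.uniform(2.0, 4.0, size=n_breaths_max)
    times = np.cumsum(gaps)
    times = times[times <= duration_s]
    vo2 = 3.5 * met * (1.0 - np.exp(-times / tau_s))
    vo2 = np.clip(vo2 + rng.normal(0.0, breath_noise_sd, times.size), 0.0, None)
    return bout, BreathSeries(times, vo2)


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate the full cohort: every subject x activity gets one bout.

    Deterministic given (config, seed).  With ``missing_fraction`` > 0 a
    matching share of bouts is skipped entirely, emulating missed visits.
    """
    rng = np.random.default_rng(config.seed)
    signatures = load_signatures()
    if config.activities is None:
        activities = list(signatures)
    else:
        activities = list(config.activities)
        unknown = set(activities) - set(signatures)
        if unknown:
            raise KeyError(f"no signature for activities: {sorted(unknown)}")
    subjects: list[SubjectProfile] = []
    for group, count in (("LPP", config.n_lpp), ("HPP", config.n_hpp)):
        for i in range(count):
            subjects.append(simulate_subject(config, group, rng, index=i))
    bouts: list[BoutRecord] = []
    for subject in subjects:
        effect = config.group_effects[subject.group]
        subject_z = rng.standard_normal()
        for activity in activities:
            skip = (
                config.missing_fraction > 0
                and rng.uniform() < config.missing_fraction
            )
            if skip:
                continue
            signature = signatures[activity]
            met = met_target(signature, effect, subject_z)
            # subjects pace the same activity differently; without this
            # jitter the exact driving frequency identifies every activity
            tilted = np.asarray(signature.gravity_axis_weights) + (
                config.orient_jitter_sd * rng.standard_normal(3)
            )
            varied = replace(
                signature,
                f0_hz=signature.f0_hz
                * float(np.exp(rng.normal(0.0, config.f0_jitter_sd))),
                amp_g=signature.amp_g
                * float(np.exp(rng.normal(0.0, config.amp_jitter_sd))),
                gravity_axis_weights=tuple(tilted.tolist()),
            )
            bout, breaths = simulate_bout(
                subject.subject_id,
                varied,
                effect,
                rng,
                duration_s=config.bout_duration_s,
                rate_hz=config.sampling_rate_hz,
                met=met,
                tau_s=config.vo2_tau_s,
                breath_noise_sd=config.breath_noise_sd,
            )
            bouts.append(
                BoutRecord(subject.subject_id, activity, bout, breaths, met)
            )
    return CohortData(config=config, subjects=subjects, bouts=bouts)


def featurize_cohort(
    data: CohortData, window_s: float = 60.0
) -> pd.DataFrame:
    """Window every bout, extract the 49 features, and join labels and METs.

    Adds ``mets`` (steady-state estimate from the simulated calorimetry, the
    regression target) and ``met_target`` (generator ground truth) per bout,
    plus the subject's performance group.
    """
    from .features import feature_table

    frames = []
    for record in data.bouts:
        windows = segment_windows(record.bout, window_s=window_s)
        if not windows:
            continue
        frame = feature_table(windows)
        ss = steady_state_vo2(
            record.breaths,
            # breath spacing can leave the span just under the bout length
            plateau_s=min(120.0, record.breaths.duration_s),
            subject_id=record.subject_id,
            activity_name=record.activity_name,
        )
        frame["mets"] = ss.mets
        frame["met_target"] = record.met_target
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    groups = {s.subject_id: s.group for s in data.subjects}
    table["group"] = table["subject_id"].map(groups)
    return table


def write_cohort(data: CohortData, outdir: str | Path) -> None:
    """Write the cohort in the plain-text formats the signals module reads."""
    outdir = Path(outdir)
    accel_dir = outdir / "accel"
    breath_dir = outdir / "breaths"
    accel_dir.mkdir(parents=True, exist_ok=True)
    breath_dir.mkdir(parents=True, exist_ok=True)
    data.subject_table().to_csv(outdir / "subjects.csv", index=False)
    data.ground_truth().to_csv(outdir / "ground_truth.csv", index=False)
    for record in data.bouts:
        slug = record.activity_name.replace(" ", "_")
        stem = f"{record.subject_id}__{slug}"
        bout = record.bout
        t = np.arange(bout.n_samples) / bout.sampling_rate_hz
        pd.DataFrame(
            {
                "time": t,
                "x": bout.samples[:, 0],
                "y": bout.samples[:, 1],
                "z": bout.samples[:, 2],
            }
        ).to_csv(accel_dir / f"{stem}.csv", index=False, float_format="%.5f")
        pd.DataFrame(
            {
                "time_s": record.breaths.timestamps_s,
                "vo2_mlkgmin": record.breaths.vo2,
            }
        ).to_csv(breath_dir / f"{stem}.csv", index=False, float_format="%.4f")
    logger.info("wrote cohort with %d bouts to %s", len(data.bouts), outdir)
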