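"""Seeded synthetic shoe-accelerometer study generator.

Emulates the two data-collection settings the pipeline is built for:

* a **lab calibration session** — eight protocol activities performed in
  protocol order for 1-4 min each by a subject wearing a heel-mounted
  sensor, with a protocol annotation log;
* a **free-living workplace session** — ~48 min of unscripted work in which
  the vast majority of time is stationary (sitting/standing) or walking,
  with an observer annotation log in the 7-class vocabulary and a workplace
  group tag.

The signal model is phenomenological, not biomechanical: a gravity
component oriented by the foot's posture, a periodic gait waveform (a small
harmonic series at the subject's cadence), sharp heel-strike impact pulses,
and white sensor noise. Only the statistical separability structure of the
activities matters for exercising the pipeline. Sitting and standing are
generated with identical parameters by default — a flat foot and the same
noise — so they are indistinguishable from a shoe sensor by construction,
reproducing the well-known sitting/standing confusability of foot-worn
sensors rather than engineering it away.

Every quantity is drawn from a ``numpy`` generator seeded deterministically
from ``(seed, subject index, mode)``, so a configuration and seed fully
determine every session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import labels as L
from .signal_io import AccelRecording, AnnotationLog, Interval


@dataclass(frozen=True)
class ActivityParams:
    """Signal-model parameters of one raw activity.

    cadence_hz is the fundamental gait frequency (0 for static postures);
    impact_g the heel-strike pulse amplitude; tilt_deg the static pitch of
    the sensor away from flat; noise_sd the white-noise SD per axis;
    vertical_ratio splits the harmonic gait energy between the z axis and
    the horizontal plane; harmonics weight the fundamental and overtones.
    """

    cadence_hz: float
    impact_g: float
    tilt_deg: float
    noise_sd: float
    vertical_ratio: float = 0.6
    gait_amp_g: float = 0.0
    harmonics: tuple[float, ...] = (1.0, 0.4, 0.2)


# Static postures: flat foot for sitting and standing (identical on purpose),
# a strongly pitched shoe for kneeling. Dynamic activities differ in cadence,
# amplitude, impact and vertical/horizontal energy split.
DEFAULT_ACTIVITY_PARAMS: dict[str, ActivityParams] = {
    L.SITTING: ActivityParams(0.0, 0.0, 0.0, 0.01),
    L.STANDING: ActivityParams(0.0, 0.0, 0.0, 0.01),
    L.KNEELING: ActivityParams(0.0, 0.0, 65.0, 0.015),
    L.WALKING_SLOW: ActivityParams(
        1.5, 0.5, 0.0, 0.05, vertical_ratio=0.6, gait_amp_g=0.35
    ),
    L.WALKING_BRISK: ActivityParams(
        2.0, 0.9, 0.0, 0.05, vertical_ratio=0.6, gait_amp_g=0.55
    ),
    L.STAIR_ASCENDING: ActivityParams(
        1.1, 0.4, 10.0, 0.05, vertical_ratio=0.85, gait_amp_g=0.45
    ),
    L.STAIR_DESCENDING: ActivityParams(
        1.3, 0.8, -10.0, 0.05, vertical_ratio=0.45, gait_amp_g=0.40
    ),
    L.WEIGHT_CARRYING: ActivityParams(
        1.2, 1.1, 0.0, 0.06, vertical_ratio=0.6, gait_amp_g=0.50
    ),
}

#: Default free-living time-share weights over the 7-class vocabulary.
#: Stationary work dominates; stationary + walking mass is 0.99.
DEFAULT_FREELIVING_WEIGHTS: dict[str, float] = {
    L.SITTING: 0.345,
    L.STANDING: 0.345,
    L.WALKING: 0.30,
    L.STAIR_ASCENDING: 0.0025,
    L.STAIR_DESCENDING: 0.0025,
    L.WEIGHT_CARRYING: 0.0025,
    L.KNEELING: 0.0025,
}

#: Mean bout durations (s) per 7-class activity in free-living sessions.
DEFAULT_MEAN_BOUT_S: dict[str, float] = {
    L.SITTING: 120.0,
    L.STANDING: 90.0,
    L.WALKING: 12.0,
    L.STAIR_ASCENDING: 15.0,
    L.STAIR_DESCENDING: 15.0,
    L.WEIGHT_CARRYING: 20.0,
    L.KNEELING: 30.0,
}


@dataclass(frozen=True)
class SubjectEffect:
    """Multiplicative random effects on a subject's gait."""

    cadence_factor: float = 1.0
    amplitude_factor: float = 1.0


@dataclass
class SyntheticConfig:
    n_subjects: int = 35
    seed: int = 0
    fs: float = 100.0
    activity_params: dict[str, ActivityParams] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_PARAMS)
    )
    # lognormal sigmas of the between-subject random effects
    cadence_sigma: float = 0.05
    amplitude_sigma: float = 0.15
    lab_duration_range_s: tuple[float, float] = (60.0, 240.0)
    freeliving_minutes: float = 48.0
    freeliving_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FREELIVING_WEIGHTS)
    )
    mean_bout_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_BOUT_S)
    )
    min_walking_bout_s: float = 3.0  # walking = continuous locomotion (> ~3 m)

    def __post_init__(self) -> None:
        w = sum(self.freeliving_weights.values())
        if not np.isclose(w, 1.0):
            raise ValueError(f"free-living mixture weights sum to {w}, expected 1")
        if any(v < 0 for v in self.freeliving_weights.values()):
            raise ValueError("mixture weights must be non-negative")
        if self.lab_duration_range_s[0] < 60.0:
            raise ValueError("lab activity durations must be >= 60 s (protocol rule)")
        if any(s < 0 for s in (self.cadence_sigma, self.amplitude_sigma)):
            raise ValueError("random-effect sigmas must be >= 0")


def _rng_for(cfg: SyntheticConfig, subject_index: int, mode: str) -> np.random.Generator:
    mode_code = {"lab": 0, "freeliving": 1}[mode]
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(subject_index), mode_code])
    )


def draw_subject_effect(cfg: SyntheticConfig, rng: np.random.Generator) -> SubjectEffect:
    return SubjectEffect(
        cadence_factor=float(rng.lognormal(0.0, cfg.cadence_sigma)),
        amplitude_factor=float(rng.lognormal(0.0, cfg.amplitude_sigma)),
    )


def _tilt_gravity(tilt_deg: float) -> np.ndarray:
    """Gravity reading of a sensor pitched by tilt_deg about the y axis."""
    t = np.radians(tilt_deg)
    return np.array([np.sin(t), 0.0, np.cos(t)])


def simulate_activity_signal(
    activity: str,
    duration: float,
    fs: float,
    effect: SubjectEffect,
    rng: np.random.Generator,
    params: dict[str, ActivityParams] | None = None,
) -> np.ndarray:
    """Generate a (round(duration*fs), 3) acceleration signal in g for one activity."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    params = DEFAULT_ACTIVITY_PARAMS if params is None else params
    try:
        p = params[activity]
    except KeyError:
        raise ValueError(f"unknown activity {activity!r}") from None

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = np.tile(_tilt_gravity(p.tilt_deg), (n, 1))

    if p.cadence_hz > 0:
        f0 = p.cadence_hz * effect.cadence_factor
        amp = p.gait_amp_g * effect.amplitude_factor
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.zeros(n)
        for h, w in enumerate(p.harmonics, start=1):
            wave += w * np.sin(2 * np.pi * f0 * h * t + phase * h)
        sig[:, 2] += amp * p.vertical_ratio * wave
        # horizontal gait component, quarter-cycle shifted (fore-aft sway)
        wave_x = np.zeros(n)
        for h, w in enumerate(p.harmonics, start=1):
            wave_x += w * np.sin(2 * np.pi * f0 * h * t + phase * h + np.pi / 2)
        sig[:, 0] += amp * (1.0 - p.vertical_ratio) * wave_x
        sig[:, 1] += 0.2 * amp * np.sin(2 * np.pi * f0 * t + phase + np.pi / 3)

        if p.impact_g > 0:
            impact = p.impact_g * effect.amplitude_factor
            width = 0.03  # 30 ms heel-strike pulse
            step_times = np.arange(phase / (2 * np.pi * f0), duration, 1.0 / f0)
            pulse = np.zeros(n)
            for st in step_times:
                lo = max(int((st - 4 * width) * fs), 0)
                hi = min(int((st + 4 * width) * fs), n)
                if hi > lo:
                    pulse[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - st) / width) ** 2)
            sig[:, 2] += impact * pulse

    sig += rng.normal(0.0, p.noise_sd, size=(n, 3))
    return sig


def simulate_lab_session(
    cfg: SyntheticConfig, subject_index: int
) -> tuple[AccelRecording, AnnotationLog]:
    """One calibration session: the 8 protocol activities in protocol order."""
    rng = _rng_for(cfg, subject_index, "lab")
    effect = draw_subject_effect(cfg, rng)
    subject_id = f"lab{subject_index:02d}"

    lo, hi = cfg.lab_duration_range_s
    parts, intervals = [], []
    t = 0.0
    for activity in L.RAW_ACTIVITIES:
        duration = float(np.round(rng.uniform(lo, hi)))
        parts.append(
            simulate_activity_signal(
                activity, duration, cfg.fs, effect, rng, cfg.activity_params
            )
        )
        intervals.append(Interval(t, t + duration, activity, source="protocol"))
        t += duration
    rec = AccelRecording(
        subject_id=subject_id, samples=np.vstack(parts), fs=cfg.fs, start_time=0.0
    )
    log = AnnotationLog(subject_id=subject_id, intervals=intervals)
    return rec, log


def _draw_bout(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[str, float]:
    """Draw one (7-class activity, duration) bout.

    Activities are chosen with probability proportional to weight / mean
    bout length, so expected *time shares* match the configured weights.
    Walking bouts are shifted-exponential with a 3 s floor (walking is
    continuous locomotion; a couple of sidesteps stay 'standing').
    """
    acts = list(cfg.freeliving_weights)
    q = np.array([cfg.freeliving_weights[a] / cfg.mean_bout_s[a] for a in acts])
    q /= q.sum()
    activity = acts[rng.choice(len(acts), p=q)]
    mean = cfg.mean_bout_s[activity]
    if activity == L.WALKING:
        floor = min(cfg.min_walking_bout_s, mean)
        duration = floor + rng.exponential(mean - floor)
    else:
        duration = rng.exponential(mean)
    return activity, max(duration, 1.0 / cfg.fs)


_FREELIVING_SIGNAL_ACTIVITY = {
    L.SITTING: L.SITTING,
    L.STANDING: L.STANDING,
    L.STAIR_ASCENDING: L.STAIR_ASCENDING,
    L.STAIR_DESCENDING: L.STAIR_DESCENDING,
    L.WEIGHT_CARRYING: L.WEIGHT_CARRYING,
    L.KNEELING: L.KNEELING,
}


def simulate_freeliving_session(
    cfg: SyntheticConfig, subject_index: int, group: str = "production"
) -> tuple[AccelRecording, AnnotationLog]:
    """One free-living workplace session with an observer annotation log.

    Bouts alternate under a semi-Markov process (exponential durations,
    activity drawn from the configured mixture); the observer log uses the
    7-class vocabulary and carries the workplace group tag. Observed walking
    is generated at a speed drawn per bout between the slow and brisk lab
    paces (free-living walking is rarely as regular as a calibration walk).
    """
    rng = _rng_for(cfg, subject_index, "freeliving")
    effect = draw_subject_effect(cfg, rng)
    subject_id = f"fl{subject_index:02d}"

    session_s = cfg.freeliving_minutes * 60.0
    parts, intervals = [], []
    t = 0.0
    while t < session_s:
        activity, duration = _draw_bout(cfg, rng)
        duration = min(duration, session_s - t)
        n = int(round(duration * cfg.fs))
        if n < 1:
            break
        duration = n / cfg.fs
        if activity == L.WALKING:
            signal_activity = L.WALKING_SLOW if rng.random() < 0.5 else L.WALKING_BRISK
        else:
            signal_activity = _FREELIVING_SIGNAL_ACTIVITY[activity]
        parts.append(
            simulate_activity_signal(
                signal_activity, duration, cfg.fs, effect, rng, cfg.activity_params
            )
        )
        intervals.append(Interval(t, t + duration, activity, source="observer"))
        t += duration
    rec = AccelRecording(
        subject_id=subject_id, samples=np.vstack(parts), fs=cfg.fs, start_time=0.0
    )
    log = AnnotationLog(subject_id=subject_id, intervals=intervals, group=group)
    return rec, log


def simulate_lab_study(cfg: SyntheticConfig) -> list[tuple[AccelRecording, AnnotationLog]]:
    """All lab calibration sessions for ``cfg.n_subjects`` subjects."""
    return [simulate_lab_session(cfg, i) for i in range(cfg.n_subjects)]


def simulate_freeliving_study(
    cfg: SyntheticConfig, groups: tuple[str, ...] = ("logistics", "production")
) -> list[tuple[AccelRecording, AnnotationLog]]:
    """All free-living sessions; subjects alternate between workplace groups."""
    return [
        simulate_freeliving_session(cfg, i, group=groups[i % len(groups)])
        for i in range(cfg.n_subjects)
    ]
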