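"""Synthetic labeled multi-sensor recordings for end-to-end testing.

Each of the 12 scripted activities is modeled per sensor as a posture DC
offset (gravity projection, m/s^2) plus a small set of sinusoids (gait or
arm-swing fundamentals and harmonics, optionally amplitude-modulated to
mimic bursty efforts such as rope jumping) plus Gaussian sensor noise.
This is deliberately not a biomechanical simulation: sinusoid-plus-noise
streams are sufficient to exercise every pathway of the time-domain feature
bank — DC-sensitive statistics separate the postures, amplitude/energy
statistics separate locomotion intensities, and frequency-linked counts
(zero crossings, slope-sign changes, Willison amplitude) separate cadences.
The two stair activities are parameterized closest together on purpose, so
they remain the hardest pair for any classifier trained downstream.

Generation is fully seeded: the same (schedule, seed) pair reproduces a
recording bit-for-bit, and per-segment phase and amplitude jitter make
different seeds behave like different subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .signal_io import (
    DEFAULT_ACTIVITY_MAP,
    PLACEMENTS,
    TRANSIENT_CODE,
    Recording,
    SensorStream,
)


@dataclass(frozen=True)
class Tone:
    """One sinusoidal component: frequency (Hz), per-axis amplitudes (m/s^2), phases."""

    freq: float
    amps: tuple[float, float, float]
    phases: tuple[float, float, float] = (0.0, 1.1, 2.3)


@dataclass(frozen=True)
class SensorModel:
    """Per-sensor signal model for one activity."""

    dc: tuple[float, float, float]
    tones: tuple[Tone, ...] = ()
    noise_std: float = 0.05
    am_depth: float = 0.0   # amplitude-modulation depth in [0, 1)
    am_rate: float = 0.0    # modulation rate, Hz


@dataclass(frozen=True)
class ActivityModel:
    """Name, label code and the per-placement sensor models of one activity."""

    name: str
    code: int
    sensors: dict[str, SensorModel] = field(default_factory=dict)

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        for sm in self.sensors.values():
            if sm.noise_std < 0:
                raise DomainError(f"{self.name}: noise std must be >= 0")
            for t in sm.tones:
                if not 0 < t.freq < nyquist:
                    raise DomainError(
                        f"{self.name}: tone frequency {t.freq} Hz outside (0, {nyquist})"
                    )


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered (activity name, duration seconds) pairs; "transient" marks breaks."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for name, dur in self.entries:
            if dur <= 0:
                raise DomainError(f"duration for {name!r} must be positive")

    def total_seconds(self) -> float:
        return sum(d for _, d in self.entries)


def _model(name, code, wrist, chest, ankle) -> ActivityModel:
    return ActivityModel(name, code, {"wrist": wrist, "chest": chest, "ankle": ankle})


def default_activity_suite() -> list[ActivityModel]:
    """The 12 scripted activities with pairwise-separable default parameters.

    Static postures differ in DC orientation only (lying vs standing share
    noise levels exactly); locomotion activities differ in cadence and in
    which sensor carries the movement energy; ascending vs descending
    stairs are deliberately the closest pair.
    """
    g = 9.81
    static_noise = 0.05
    return [
        _model(
            "lying", 1,
            SensorModel((0.3, 0.2, g), noise_std=static_noise),
            SensorModel((0.0, 0.4, g), noise_std=static_noise),
            SensorModel((0.2, 0.0, g), noise_std=static_noise),
        ),
        _model(
            "sitting", 2,
            SensorModel((5.2, 7.8, 2.0), noise_std=0.07),
            SensorModel((1.5, g, 1.0), noise_std=0.07),
            SensorModel((6.5, 6.8, 2.2), noise_std=0.07),
        ),
        # standing differs from lying only in the gravity direction
        _model(
            "standing", 3,
            SensorModel((0.3, g, 0.2), noise_std=static_noise),
            SensorModel((0.0, g, 0.4), noise_std=static_noise),
            SensorModel((0.2, g, 0.0), noise_std=static_noise),
        ),
        _model(
            "walking", 4,
            SensorModel((1.0, g, 0.5), (Tone(2.0, (1.3, 0.9, 0.6)), Tone(4.0, (0.4, 0.3, 0.2))), 0.30),
            SensorModel((0.5, g, 0.8), (Tone(2.0, (0.8, 0.6, 1.0)),), 0.25),
            SensorModel((0.8, g, 0.3), (Tone(2.0, (3.6, 2.2, 1.5)), Tone(4.0, (1.1, 0.7, 0.5))), 0.35),
        ),
        _model(
            "running", 5,
            SensorModel((1.5, g, 0.8), (Tone(2.8, (3.2, 2.1, 2.0)), Tone(5.6, (1.0, 0.8, 0.6))), 0.60),
            SensorModel((0.8, g, 1.2), (Tone(2.8, (4.0, 2.6, 2.2)),), 0.55),
            SensorModel((1.2, g, 0.5), (Tone(2.8, (8.0, 5.2, 4.1)), Tone(5.6, (2.4, 1.6, 1.2))), 0.70),
        ),
        _model(
            "cycling", 6,
            SensorModel((6.0, 7.0, 1.5), (Tone(1.4, (0.5, 0.3, 0.3)),), 0.22),
            SensorModel((3.0, 9.0, 1.2), (Tone(1.4, (0.6, 0.4, 0.3)),), 0.20),
            SensorModel((5.5, 7.5, 2.0), (Tone(1.4, (3.1, 2.4, 1.1)), Tone(2.8, (0.8, 0.6, 0.3))), 0.30),
        ),
        # Nordic walking: walking cadence, but the poles drive the wrist hard
        _model(
            "nordic_walking", 7,
            SensorModel((1.2, g, 0.6), (Tone(2.0, (3.3, 2.1, 1.6)), Tone(4.0, (0.9, 0.6, 0.4))), 0.35),
            SensorModel((0.6, g, 0.9), (Tone(2.0, (1.0, 0.7, 1.1)),), 0.28),
            SensorModel((0.9, g, 0.4), (Tone(2.0, (3.4, 2.1, 1.4)), Tone(4.0, (1.0, 0.6, 0.5))), 0.35),
        ),
        _model(
            "ascending_stairs", 12,
            SensorModel((1.1, 9.2, 1.8), (Tone(1.6, (1.1, 0.8, 0.55)),), 0.35),
            SensorModel((0.7, 9.3, 1.6), (Tone(1.6, (1.0, 0.6, 0.8)),), 0.32),
            SensorModel((1.0, 9.2, 1.5), (Tone(1.6, (3.0, 2.2, 1.6)), Tone(3.2, (0.9, 0.6, 0.4))), 0.40),
        ),
        # deliberately the closest neighbor of ascending_stairs
        _model(
            "descending_stairs", 13,
            SensorModel((1.2, 9.1, 1.9), (Tone(1.75, (1.2, 0.75, 0.6)),), 0.37),
            SensorModel((0.75, 9.2, 1.7), (Tone(1.75, (1.05, 0.65, 0.75)),), 0.34),
            SensorModel((1.1, 9.1, 1.6), (Tone(1.75, (3.3, 2.0, 1.8)), Tone(3.5, (1.0, 0.7, 0.45))), 0.42),
        ),
        _model(
            "vacuum_cleaning", 16,
            SensorModel((2.0, 8.8, 2.5), (Tone(1.0, (1.6, 1.1, 0.8)),), 0.20),
            SensorModel((1.0, 9.4, 1.5), (Tone(0.8, (0.5, 0.3, 0.4)),), 0.15),
            SensorModel((1.5, 9.0, 1.0), (Tone(0.8, (0.9, 0.6, 0.4)),), 0.18),
        ),
        _model(
            "ironing", 17,
            SensorModel((3.0, 8.5, 2.8), (Tone(0.8, (1.3, 0.9, 0.5)),), 0.12),
            SensorModel((0.2, g, 0.5), (), 0.08),
            SensorModel((0.3, g, 0.1), (), 0.06),
        ),
        _model(
            "rope_jumping", 24,
            SensorModel((1.8, 8.5, 2.0), (Tone(3.5, (5.0, 3.2, 3.0)),), 0.70, am_depth=0.8, am_rate=0.25),
            SensorModel((1.0, 9.0, 1.5), (Tone(3.5, (6.0, 4.1, 3.2)),), 0.65, am_depth=0.8, am_rate=0.25),
            SensorModel((1.4, 8.8, 1.0), (Tone(3.5, (9.0, 6.1, 5.0)), Tone(7.0, (2.5, 1.6, 1.2))), 0.80,
                        am_depth=0.8, am_rate=0.25),
        ),
    ]


#: Signal model used for breaks between activities (quiet standing with fidgeting).
TRANSIENT_MODEL = ActivityModel(
    "transient", TRANSIENT_CODE,
    {p: SensorModel((0.5, 9.5, 0.8), (Tone(0.5, (0.4, 0.3, 0.3)),), 0.4) for p in PLACEMENTS},
)


def default_schedule(
    seconds_per_activity: float = 60.0, transient_seconds: float = 0.0
) -> ProtocolSchedule:
    """One bout per activity in code order, optionally separated by breaks."""
    entries: list[tuple[str, float]] = []
    for name in DEFAULT_ACTIVITY_MAP.values():
        if entries and transient_seconds > 0:
            entries.append(("transient", transient_seconds))
        entries.append((name, seconds_per_activity))
    return ProtocolSchedule(tuple(entries))


def generate(
    schedule: ProtocolSchedule,
    suite: list[ActivityModel] | None = None,
    sampling_rate: float = 100.0,
    seed: int = 0,
    missing_rate: float = 0.0,
    subject_id: str = "synthetic",
) -> Recording:
    """Render a schedule into a seeded three-sensor :class:`Recording`.

    Per segment, each tone receives a random phase offset and a ~5%
    amplitude jitter (a cheap stand-in for between-bout variability); the
    optional ``missing_rate`` drops samples to NaN independently per sensor
    and axis, emulating wireless dropouts.
    """
    suite = suite if suite is not None else default_activity_suite()
    by_name = {m.name: m for m in suite}
    by_name.setdefault("transient", TRANSIENT_MODEL)
    for m in by_name.values():
        m.validate(sampling_rate)
    for name, _ in schedule.entries:
        if name not in by_name:
            raise DomainError(f"schedule names unknown activity {name!r}")

    rng = np.random.default_rng(seed)
    seg_lengths = [int(round(d * sampling_rate)) for _, d in schedule.entries]
    total = sum(seg_lengths)
    labels = np.empty(total, dtype=np.int64)
    data = {p: np.empty((total, 3)) for p in PLACEMENTS}

    pos = 0
    for (name, _), n in zip(schedule.entries, seg_lengths):
        model = by_name[name]
        t = np.arange(n) / sampling_rate
        labels[pos : pos + n] = model.code
        for p in PLACEMENTS:
            sm = model.sensors.get(p)
            if sm is None:
                raise DomainError(f"activity {name!r} lacks a model for sensor {p!r}")
            sig = np.zeros((n, 3))
            for tone in sm.tones:
                phase_jitter = rng.uniform(0, 2 * np.pi)
                amp_jitter = 1.0 + 0.05 * rng.standard_normal()
                for a in range(3):
                    sig[:, a] += (
                        tone.amps[a] * amp_jitter
                        * np.sin(2 * np.pi * tone.freq * t + tone.phases[a] + phase_jitter)
                    )
            if sm.am_depth > 0 and sm.am_rate > 0:
                env = 1.0 + sm.am_depth * np.sin(
                    2 * np.pi * sm.am_rate * t + rng.uniform(0, 2 * np.pi)
                )
                sig *= env[:, None]
            sig += np.array(sm.dc)
            sig += sm.noise_std * rng.standard_normal((n, 3))
            data[p][pos : pos + n] = sig
        pos += n

    if missing_rate > 0:
        for p in PLACEMENTS:
            mask = rng.random((total, 3)) < missing_rate
            data[p][mask] = np.nan

    sensors = {p: SensorStream(p, data[p][:, 0], data[p][:, 1], data[p][:, 2]) for p in PLACEMENTS}
    timestamps = np.arange(total) / sampling_rate
    return Recording(subject_id, sampling_rate, sensors, labels, timestamps)


def generate_subjects(
    n_subjects: int,
    seconds_per_activity: float = 60.0,
    sampling_rate: float = 100.0,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> list[Recording]:
    """Independent per-subject recordings (seeds derived as seed + subject index)."""
    schedule = default_schedule(seconds_per_activity)
    return [
        generate(
            schedule, sampling_rate=sampling_rate, seed=seed + i,
            missing_rate=missing_rate, subject_id=f"synthetic-{i}",
        )
        for i in range(n_subjects)
    ]
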