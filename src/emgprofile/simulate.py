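"""Synthetic sEMG generator with analytic ground truth.

The signal model is a band-limited (20–450 Hz by default) zero-mean
Gaussian carrier, amplitude-modulated by a task schedule: within each
schedule segment the carrier is rescaled so its realized RMS equals the
segment's target amplitude, expressed in %MVC of a configurable
reference.  Because the per-segment scaling is exact by construction,
the ground truth (mean envelope, duration-weighted APDF, scheduled rest
fraction) is computed analytically from the schedule, never from the
realized noise.

Cohort generation emulates the study design: two worker groups of
configurable size, five muscles each, with group × muscle mean %MVC
levels, between-subject scatter, and a rest/active bout structure.  The
defaults mirror the dairy-worker comparison: 26 large-herd and 39
small-herd subjects, one-hour work recordings, group levels taken from
the published model estimates.  Tests and examples pass smaller,
explicit configurations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import io as eio
from .calibration import CalibrationSet
from .errors import ValidationError
from .io import CohortManifest, EmgRecording, ManifestEntry, MUSCLES

#: Reporting-convention %MR rest rule, reused for scheduled ground truth.
REST_THRESHOLD_PCT = 0.5
MIN_GAP_DURATION_S = 0.25


@dataclass(frozen=True)
class Segment:
    """One schedule segment: a task label, duration, and target %MVC."""

    label: str
    duration: float
    amplitude: float  # target envelope amplitude, %MVC

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValidationError(f"segment {self.label!r}: duration must be positive")
        if self.amplitude < 0:
            raise ValidationError(f"segment {self.label!r}: amplitude must be >= 0")


@dataclass(frozen=True)
class TaskSchedule:
    """Ordered segments tiling a recording exactly."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("schedule must contain at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def mean_envelope(self) -> float:
        """Duration-weighted mean amplitude (%MVC)."""
        return float(
            sum(s.duration * s.amplitude for s in self.segments) / self.total_duration
        )

    def quantile(self, p: float) -> float:
        """Duration-weighted amplitude quantile, midpoint convention.

        The amplitude distribution is a step function; a probability
        falling exactly on a step boundary returns the midpoint of the
        adjacent amplitude levels.
        """
        if not (0.0 < p < 1.0):
            raise ValidationError(f"probability must be in (0, 1), got {p}")
        levels: dict[float, float] = {}
        for s in self.segments:
            levels[s.amplitude] = levels.get(s.amplitude, 0.0) + s.duration
        amps = sorted(levels)
        weights = np.array([levels[a] for a in amps]) / self.total_duration
        cum = np.cumsum(weights)
        for i, c in enumerate(cum[:-1]):
            if abs(p - c) <= 1e-12:
                return (amps[i] + amps[i + 1]) / 2.0
            if p < c:
                return amps[i]
        return amps[-1]

    def rest_fraction(
        self,
        threshold: float = REST_THRESHOLD_PCT,
        min_gap_duration: float = MIN_GAP_DURATION_S,
    ) -> float:
        """Scheduled %MR: share of time in merged sub-threshold bouts of
        at least ``min_gap_duration`` (same inclusion rule as the metric)."""
        rest_time = 0.0
        bout = 0.0
        for s in self.segments:
            if s.amplitude <= threshold:
                bout += s.duration
            else:
                if bout >= min_gap_duration - 1e-12:
                    rest_time += bout
                bout = 0.0
        if bout >= min_gap_duration - 1e-12:
            rest_time += bout
        return float(100.0 * rest_time / self.total_duration)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic per-recording truth, derived from the schedule only."""

    mean_envelope_pct: float
    apdf_pct: dict[float, float]
    rest_fraction_pct: float
    schedule: TaskSchedule

    @classmethod
    def from_schedule(
        cls, schedule: TaskSchedule, percentiles: tuple[float, ...] = (0.10, 0.50, 0.90)
    ) -> "GroundTruth":
        return cls(
            mean_envelope_pct=schedule.mean_envelope(),
            apdf_pct={p: schedule.quantile(p) for p in percentiles},
            rest_fraction_pct=schedule.rest_fraction(),
            schedule=schedule,
        )


@dataclass(frozen=True)
class GroupSpec:
    """One worker group of a simulated cohort."""

    n_subjects: int
    muscle_levels: dict[str, float]       # mean %MVC per muscle (duration-weighted)
    between_subject_sd: float = 6.0       # %MVC scatter of subject levels
    rest_fraction: float = 0.10           # share of work time at rest
    rest_bout_duration: float = 1.5       # seconds per rest bout
    rest_fraction_sd: float = 0.02        # between-subject scatter of rest share

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("each group needs at least one subject")
        if not (0.0 <= self.rest_fraction < 1.0):
            raise ValidationError("rest_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort block: groups, muscles, and the work-recording duration."""

    groups: dict[str, GroupSpec]
    muscles: tuple[str, ...] = MUSCLES
    work_duration: float = 3600.0

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValidationError("cohort needs at least one group")
        for name, spec in self.groups.items():
            missing = [m for m in self.muscles if m not in spec.muscle_levels]
            if missing:
                raise ValidationError(f"group {name!r} lacks levels for muscles {missing}")


@dataclass(frozen=True)
class SimulationConfig:
    """Simulator parameters; defaults are the study conditions."""

    seed: int = 0
    sampling_rate: float = 1000.0
    noise_band: tuple[float, float] = (20.0, 450.0)
    mvc_reference_amplitude: float = 1.0  # instrument units at 100 %MVC
    baseline_level: float = 0.2           # %MVC-equivalent resting activity
    baseline_duration: float = 30.0
    fmvc_trial_duration: float = 5.0
    n_fmvc_trials: int = 3
    cohort: CohortSpec | None = None

    def __post_init__(self) -> None:
        low, high = self.noise_band
        if not (0 < low < high < self.sampling_rate / 2):
            raise ValidationError(
                f"noise band {self.noise_band} must satisfy 0 < low < high < "
                f"Nyquist ({self.sampling_rate / 2} Hz)"
            )
        if self.mvc_reference_amplitude <= 0:
            raise ValidationError("mvc_reference_amplitude must be positive")


#: Group × muscle mean %fMVC levels used by the default cohort, taken from
#: the published model estimates of mean RMS activity.
DEFAULT_GROUP_LEVELS: dict[str, dict[str, float]] = {
    "large_herd_US": {
        "upper_trapezius": 13.47,
        "anterior_deltoid": 9.62,
        "biceps_brachii": 19.32,
        "wrist_flexors": 12.62,
        "wrist_extensors": 13.90,
    },
    "small_herd_IT": {
        "upper_trapezius": 8.03,
        "anterior_deltoid": 8.25,
        "biceps_brachii": 6.85,
        "wrist_flexors": 5.63,
        "wrist_extensors": 15.06,
    },
}


def default_cohort_spec(
    n_subjects: tuple[int, int] = (26, 39),
    work_duration: float = 3600.0,
) -> CohortSpec:
    """The study-shaped cohort: two groups, five muscles, published
    group levels, rest fractions matching the reported %MR contrast."""
    return CohortSpec(
        groups={
            "large_herd_US": GroupSpec(
                n_subjects=n_subjects[0],
                muscle_levels=DEFAULT_GROUP_LEVELS["large_herd_US"],
                rest_fraction=0.13,
            ),
            "small_herd_IT": GroupSpec(
                n_subjects=n_subjects[1],
                muscle_levels=DEFAULT_GROUP_LEVELS["small_herd_IT"],
                rest_fraction=0.05,
            ),
        },
        work_duration=work_duration,
    )


def child_rng(master_seed: int, *path: int | str) -> np.random.Generator:
    """Deterministic child stream: SeedSequence(master, spawn_key=path).

    String path elements hash to stable 32-bit keys so subject/muscle
    labels can address streams directly.
    """
    key = tuple(
        p if isinstance(p, int) else int.from_bytes(str(p).encode()[:4].ljust(4, b"_"), "big")
        for p in path
    )
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def rest_work_schedule(
    total_duration: float,
    rest_fraction: float,
    rest_bout_duration: float,
    active_amplitude: float,
    active_label: str = "task",
) -> TaskSchedule:
    """Alternating active/rest schedule with the requested rest share.

    Rest bouts of ``rest_bout_duration`` alternate with active bouts
    sized so that rest occupies ``rest_fraction`` of each cycle; the
    final segment is trimmed to tile ``total_duration`` exactly.
    """
    if not (total_duration > 0):
        raise ValidationError("total_duration must be positive")
    if rest_fraction <= 0:
        return TaskSchedule((Segment(active_label, total_duration, active_amplitude),))
    if not (rest_fraction < 1):
        raise ValidationError("rest_fraction must be < 1")
    active_duration = rest_bout_duration * (1.0 - rest_fraction) / rest_fraction
    segments: list[Segment] = []
    t = 0.0
    while t < total_duration - 1e-9:
        for label, dur, amp in (
            (active_label, active_duration, active_amplitude),
            ("rest", rest_bout_duration, 0.0),
        ):
            dur = min(dur, total_duration - t)
            if dur <= 1e-9:
                break
            segments.append(Segment(label, dur, amp))
            t += dur
    return TaskSchedule(tuple(segments))


def milking_schedule(
    n_cycles: int = 10,
    rest_between_cows: float = 1.5,
    amplitudes: dict[str, float] | None = None,
) -> TaskSchedule:
    """A stylized milking-parlor cycle: pre-dip, strip, wipe, attach,
    post-dip, then a micro-break before the next cow."""
    amps = {
        "pre_dipping": 12.0,
        "stripping": 25.0,
        "wiping": 18.0,
        "attaching": 30.0,
        "post_dipping": 12.0,
    }
    if amplitudes:
        amps.update(amplitudes)
    durations = {
        "pre_dipping": 4.0,
        "stripping": 6.0,
        "wiping": 5.0,
        "attaching": 6.0,
        "post_dipping": 4.0,
    }
    segments: list[Segment] = []
    for _ in range(n_cycles):
        for task, dur in durations.items():
            segments.append(Segment(task, dur, amps[task]))
        segments.append(Segment("rest", rest_between_cows, 0.0))
    return TaskSchedule(tuple(segments))


def _band_limited_carrier(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    sos = signal.butter(
        4, list(config.noise_band), btype="bandpass", fs=config.sampling_rate, output="sos"
    )
    return signal.sosfiltfilt(sos, rng.standard_normal(n))


def simulate_recording(
    config: SimulationConfig,
    schedule: TaskSchedule,
    rng: np.random.Generator | None = None,
    *,
    subject_id: str = "",
    group: str = "",
    muscle: str = "",
    session_kind: str = "work",
    percentiles: tuple[float, ...] = (0.10, 0.50, 0.90),
) -> tuple[EmgRecording, GroundTruth]:
    """Generate one amplitude-modulated recording plus its ground truth.

    Per-segment RMS is exact by construction: each segment's carrier
    slice is rescaled to the target RMS
    ``(amplitude/100) * mvc_reference_amplitude``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    boundaries = np.round(
        np.cumsum([0.0] + [s.duration for s in schedule.segments]) * fs
    ).astype(int)
    n = int(boundaries[-1])
    if n < 1:
        raise ValidationError("schedule too short for one sample")
    x = _band_limited_carrier(rng, n, config)
    for seg, a, b in zip(schedule.segments, boundaries[:-1], boundaries[1:]):
        target = seg.amplitude / 100.0 * config.mvc_reference_amplitude
        if target == 0.0 or b <= a:
            x[a:b] = 0.0
            continue
        realized = np.sqrt(np.mean(np.square(x[a:b])))
        x[a:b] *= target / realized
    rec = EmgRecording(
        samples=x,
        sampling_rate=fs,
        subject_id=subject_id,
        group=group,
        muscle=muscle,
        session_kind=session_kind,
    )
    return rec, GroundTruth.from_schedule(schedule, percentiles)


def simulate_calibration(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    subject_id: str = "",
    group: str = "",
    muscle: str = "",
) -> CalibrationSet:
    """Baseline (30 s at a low resting level) plus maximal-effort trials
    (100 %MVC, 5 s each by default), with independent child streams."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    baseline_schedule = TaskSchedule(
        (Segment("baseline", config.baseline_duration, config.baseline_level),)
    )
    baseline, _ = simulate_recording(
        config, baseline_schedule, rng,
        subject_id=subject_id, group=group, muscle=muscle, session_kind="baseline",
    )
    trials = []
    for _ in range(config.n_fmvc_trials):
        trial_schedule = TaskSchedule(
            (Segment("fmvc", config.fmvc_trial_duration, 100.0),)
        )
        trial, _ = simulate_recording(
            config, trial_schedule, rng,
            subject_id=subject_id, group=group, muscle=muscle, session_kind="fmvc_trial",
        )
        trials.append(trial)
    return CalibrationSet(
        subject_id=subject_id, muscle=muscle, baseline=baseline, fmvc_trials=tuple(trials)
    )


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
) -> tuple[CohortManifest, dict[tuple[str, str], GroundTruth], pd.DataFrame]:
    """Write a full synthetic cohort in the pipeline's input formats.

    Per-subject muscle levels are drawn as group truth plus
    Normal(0, between-subject SD), floored at zero; each subject/muscle
    gets a work recording, a baseline, and fMVC trials, all written via
    the I/O layer.  Returns the manifest, per-recording ground truths,
    and the true group × muscle mean table for recovery scoring.
    """
    if config.cohort is None:
        raise ValidationError("config.cohort must be set for cohort simulation")
    spec = config.cohort
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    signals = out_dir / "signals"
    signals.mkdir(exist_ok=True)

    entries: list[ManifestEntry] = []
    truths: dict[tuple[str, str], GroundTruth] = {}
    truth_rows: list[dict] = []
    for gi, (group, gspec) in enumerate(spec.groups.items()):
        for m in spec.muscles:
            truth_rows.append(
                {"group": group, "muscle": m, "true_mean_pct": gspec.muscle_levels[m]}
            )
        for si in range(gspec.n_subjects):
            sid = f"{group}_{si + 1:02d}"
            level_rng = child_rng(config.seed, gi, si, 0)
            for mi, m in enumerate(spec.muscles):
                level = gspec.muscle_levels[m] + level_rng.normal(0.0, gspec.between_subject_sd)
                level = max(level, 0.0)
                f = gspec.rest_fraction
                if f > 0 and gspec.rest_fraction_sd > 0:
                    f = float(np.clip(f + level_rng.normal(0.0, gspec.rest_fraction_sd), 0.005, 0.9))
                active = level / (1.0 - f) if f < 1.0 else 0.0
                schedule = rest_work_schedule(
                    spec.work_duration, f, gspec.rest_bout_duration, active
                )
                work_rng = child_rng(config.seed, gi, si, mi, 1)
                work, truth = simulate_recording(
                    config, schedule, work_rng,
                    subject_id=sid, group=group, muscle=m, session_kind="work",
                )
                cal_rng = child_rng(config.seed, gi, si, mi, 2)
                cal = simulate_calibration(
                    config, cal_rng, subject_id=sid, group=group, muscle=m
                )
                stem = f"{sid}_{m}"
                work_path = eio.write_recording(work, signals / f"{stem}_work.csv")
                base_path = eio.write_recording(cal.baseline, signals / f"{stem}_baseline.csv")
                trial_paths = tuple(
                    eio.write_recording(t, signals / f"{stem}_fmvc{k + 1}.csv")
                    for k, t in enumerate(cal.fmvc_trials)
                )
                entries.append(
                    ManifestEntry(
                        subject_id=sid, group=group, muscle=m,
                        work_path=work_path, baseline_path=base_path, fmvc_paths=trial_paths,
                    )
                )
                truths[(sid, m)] = truth

    manifest = CohortManifest(
        entries=entries,
        metadata={"seed": config.seed, "generator": "emgprofile.simulate", "kind": "synthetic"},
    )
    eio.write_manifest(manifest, out_dir / "manifest.yaml")
    truth_table = pd.DataFrame(truth_rows)
    truth_table.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truths, truth_table
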