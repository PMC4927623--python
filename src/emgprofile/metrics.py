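"""Muscle activity profile metrics and exposure-limit classification.

The activity profile of one work recording comprises five numbers
computed from the %fMVC-normalized RMS envelope:

* mean RMS — the average normalized amplitude;
* APDF p10 / p50 / p90 — the 10th, 50th and 90th empirical percentiles of
  the amplitude distribution, summarizing static, median and peak load;
* %MR — percent muscular rest, the share of recording time spent in
  contiguous bouts where the envelope stays at or below 0.5 %fMVC for at
  least 0.25 s.

Profiles are then screened against published occupational upper-limit
values for sustained work (task durations of one hour or more): static
load (p10) should not exceed 2 %MVC and must not exceed 5 %MVC; median
load (p50) 10 and 14 %MVC; peak load (p90) 50 and 70 %MVC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDurationError, ResolutionError, ValidationError
from .io import EmgRecording

#: (should-not-exceed, must-not-exceed) limits in %MVC, by load category.
EXPOSURE_LIMITS: dict[str, tuple[float, float]] = {
    "static": (2.0, 5.0),   # judged on APDF p10
    "median": (10.0, 14.0), # judged on APDF p50
    "peak": (50.0, 70.0),   # judged on APDF p90
}

WITHIN = "within"
EXCEEDS_SHOULD_NOT = "exceeds_should_not"
EXCEEDS_MUST_NOT = "exceeds_must_not"


@dataclass(frozen=True)
class RmsEnvelope:
    """Moving-window RMS amplitude estimate on a regular time grid."""

    values: np.ndarray
    window_duration: float
    step_duration: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValidationError("envelope values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values)):
            raise ValidationError("envelope contains non-finite values")
        if np.any(values < 0):
            raise ValidationError("envelope values must be non-negative")
        if not (0 < self.step_duration <= self.window_duration):
            raise ValidationError(
                f"need 0 < step ({self.step_duration}) <= window ({self.window_duration})"
            )

    @property
    def envelope_rate(self) -> float:
        """Envelope values per second (1 / step)."""
        return 1.0 / self.step_duration

    @property
    def duration(self) -> float:
        """Time spanned by the envelope grid (count × step)."""
        return self.values.size * self.step_duration


class NormalizedEnvelope(RmsEnvelope):
    """An RMS envelope whose values are in %fMVC."""


@dataclass(frozen=True)
class MuscleActivityProfile:
    """The five summary metrics for one subject/muscle work recording."""

    mean_rms: float
    apdf_p10: float
    apdf_p50: float
    apdf_p90: float
    percent_rest: float
    recording_duration: float

    def __post_init__(self) -> None:
        if not (self.apdf_p10 <= self.apdf_p50 <= self.apdf_p90):
            raise ValidationError("APDF percentiles must be monotone: p10 <= p50 <= p90")
        if not (0.0 <= self.percent_rest <= 100.0):
            raise ValidationError("percent_rest must lie in [0, 100]")
        for name in ("mean_rms", "apdf_p10", "apdf_p50", "apdf_p90"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_rms": self.mean_rms,
            "apdf_p10": self.apdf_p10,
            "apdf_p50": self.apdf_p50,
            "apdf_p90": self.apdf_p90,
            "percent_rest": self.percent_rest,
        }


@dataclass(frozen=True)
class ExposureAssessment:
    """Per-load-category flags against the published limit values."""

    static: str
    median: str
    peak: str

    def __post_init__(self) -> None:
        valid = {WITHIN, EXCEEDS_SHOULD_NOT, EXCEEDS_MUST_NOT}
        for name in ("static", "median", "peak"):
            if getattr(self, name) not in valid:
                raise ValidationError(f"invalid exposure flag for {name}")


@dataclass(frozen=True)
class ProcessingParams:
    """Envelope and rest-detection parameters for profile construction."""

    window_duration: float = 0.1
    step_duration: float = 0.05
    rest_threshold: float = 0.5   # %fMVC, inclusive
    min_gap_duration: float = 0.25  # seconds
    percentiles: tuple[float, ...] = (0.10, 0.50, 0.90)
    subtract_baseline: bool = False
    prefilter_band: tuple[float, float] | None = None


def compute_rms_envelope(
    recording: EmgRecording,
    window_duration: float = 0.1,
    step_duration: float = 0.05,
) -> RmsEnvelope:
    """Moving-window RMS of a raw recording.

    The k-th value is ``sqrt(mean(x**2))`` over samples
    ``[k*S, k*S + W)``; a trailing partial window is discarded, never
    padded, so the envelope has ``floor((N - W)/S) + 1`` values.
    """
    fs = recording.sampling_rate
    w = int(round(window_duration * fs))
    s = int(round(step_duration * fs))
    if w < 1 or s < 1 or s > w:
        raise ValidationError(
            f"need 0 < step ({step_duration}) <= window ({window_duration}) at {fs} Hz"
        )
    n = recording.n_samples
    if n < w:
        raise InsufficientDurationError(
            f"recording of {recording.duration:.3f} s is shorter than one "
            f"{window_duration:.3f} s RMS window"
        )
    k = (n - w) // s + 1
    # O(n) via cumulative sum of squares; clip tiny negative rounding noise
    csum = np.concatenate(([0.0], np.cumsum(np.square(recording.samples))))
    starts = np.arange(k) * s
    sums = csum[starts + w] - csum[starts]
    values = np.sqrt(np.maximum(sums / w, 0.0))
    return RmsEnvelope(values=values, window_duration=w / fs, step_duration=s / fs)


def mean_rms(envelope: RmsEnvelope) -> float:
    """Arithmetic mean of the envelope values."""
    return float(np.mean(envelope.values))


def compute_apdf(
    envelope: RmsEnvelope,
    percentiles: Sequence[float] = (0.10, 0.50, 0.90),
) -> dict[float, float]:
    """Empirical amplitude quantiles (linear interpolation between order
    statistics), keyed by probability and monotone in it."""
    ps = list(percentiles)
    if not ps:
        raise ValidationError("at least one percentile required")
    for p in ps:
        if not (0.0 < p < 1.0):
            raise ValidationError(f"percentile probability must be in (0, 1), got {p}")
    q = np.quantile(envelope.values, ps, method="linear")
    return {p: float(v) for p, v in zip(ps, q)}


def percent_muscular_rest(
    envelope: RmsEnvelope,
    amplitude_threshold: float = 0.5,
    min_gap_duration: float = 0.25,
) -> float:
    """Percent of recording time in qualifying rest gaps.

    A gap is a maximal run of consecutive envelope values at or below
    ``amplitude_threshold``; a run of n values spans ``n * step`` seconds
    and counts only when that span reaches ``min_gap_duration``.
    """
    if not (amplitude_threshold > 0) or not (min_gap_duration > 0):
        raise ValidationError("thresholds must be positive")
    step = envelope.step_duration
    if min_gap_duration < step - 1e-12:
        raise ResolutionError(
            f"min_gap_duration ({min_gap_duration} s) is below the envelope step "
            f"({step} s); recompute the envelope with a smaller step"
        )
    rest = envelope.values <= amplitude_threshold
    # run-length encode the rest mask
    edges = np.diff(np.concatenate(([0], rest.view(np.int8), [0])))
    run_starts = np.flatnonzero(edges == 1)
    run_ends = np.flatnonzero(edges == -1)
    spans = (run_ends - run_starts) * step
    qualifying = spans[spans >= min_gap_duration - 1e-12]
    return float(100.0 * qualifying.sum() / (rest.size * step))


def build_profile(
    recording: EmgRecording,
    cal,
    params: ProcessingParams = ProcessingParams(),
) -> MuscleActivityProfile:
    """Full per-recording pipeline: envelope → %fMVC → five metrics."""
    from .calibration import bandpass_filter, normalize_envelope  # local: avoids cycle

    if params.prefilter_band is not None:
        recording = bandpass_filter(recording, *params.prefilter_band)
    raw_env = compute_rms_envelope(recording, params.window_duration, params.step_duration)
    env = normalize_envelope(raw_env, cal, subtract_baseline=params.subtract_baseline)
    apdf = compute_apdf(env, params.percentiles)
    ps = sorted(params.percentiles)
    return MuscleActivityProfile(
        mean_rms=mean_rms(env),
        apdf_p10=apdf[ps[0]],
        apdf_p50=apdf[ps[1]],
        apdf_p90=apdf[ps[2]],
        percent_rest=percent_muscular_rest(env, params.rest_threshold, params.min_gap_duration),
        recording_duration=recording.duration,
    )


def _flag(value: float, limits: tuple[float, float]) -> str:
    should_not, must_not = limits
    if value > must_not:
        return EXCEEDS_MUST_NOT
    if value > should_not:
        return EXCEEDS_SHOULD_NOT
    return WITHIN


def classify_exposure(profile: MuscleActivityProfile) -> ExposureAssessment:
    """Screen a profile against the static/median/peak load limits.

    "Exceed" is strict: a value exactly at a limit is permissible.
    """
    return ExposureAssessment(
        static=_flag(profile.apdf_p10, EXPOSURE_LIMITS["static"]),
        median=_flag(profile.apdf_p50, EXPOSURE_LIMITS["median"]),
        peak=_flag(profile.apdf_p90, EXPOSURE_LIMITS["peak"]),
    )
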