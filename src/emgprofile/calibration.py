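"""fMVC calibration and %fMVC normalization.

Each subject/muscle contributes a 30-s resting baseline and at least three
maximal-effort (fMVC) trials.  The normalization denominator is the
middle-3-s RMS of the strongest trial; work-period envelopes are then
expressed as a percentage of that value.  Fewer than three trials is a
protocol deviation that warrants a warning, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateCalibrationError, InsufficientDurationError, ValidationError
from .io import EmgRecording
from .metrics import NormalizedEnvelope, RmsEnvelope

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationSet:
    """Baseline rest recording plus fMVC trials for one subject/muscle."""

    subject_id: str
    muscle: str
    baseline: EmgRecording
    fmvc_trials: tuple[EmgRecording, ...]

    def __post_init__(self) -> None:
        if len(self.fmvc_trials) < 1:
            raise ValidationError("calibration requires at least one fMVC trial")
        rates = {self.baseline.sampling_rate} | {t.sampling_rate for t in self.fmvc_trials}
        if len(rates) > 1:
            raise ValidationError(f"baseline and trials disagree on sampling rate: {sorted(rates)}")


@dataclass(frozen=True)
class CalibrationResult:
    """Normalization constants for one subject/muscle.

    ``fmvc_value`` is the middle-window RMS of the best trial and serves
    as the %fMVC denominator; ``baseline_rms`` documents the resting floor.
    """

    fmvc_value: float
    per_trial_values: tuple[float, ...]
    baseline_rms: float
    trial_count: int


def middle_window_rms(recording: EmgRecording, window_duration: float = 3.0) -> float:
    """RMS over the centered ``window_duration`` span of a recording.

    The window start is ``floor((N - W) / 2)`` samples, i.e. ties round
    toward the beginning.
    """
    if not (window_duration > 0):
        raise ValidationError("window_duration must be positive")
    w = int(round(window_duration * recording.sampling_rate))
    n = recording.n_samples
    if n < w:
        raise InsufficientDurationError(
            f"recording of {recording.duration:.3f} s is shorter than the "
            f"{window_duration:.3f} s analysis window"
        )
    start = (n - w) // 2
    x = recording.samples[start : start + w]
    return float(np.sqrt(np.mean(np.square(x))))


def calibrate(
    cal: CalibrationSet,
    window_duration: float = 3.0,
    aggregate: str = "max",
) -> CalibrationResult:
    """Derive the fMVC normalization constant from a calibration set.

    ``aggregate`` selects how per-trial middle-window RMS values combine
    into the denominator: ``max`` (MVC convention, default) or ``mean``.
    """
    per_trial = tuple(middle_window_rms(t, window_duration) for t in cal.fmvc_trials)
    if aggregate == "max":
        fmvc = max(per_trial)
    elif aggregate == "mean":
        fmvc = float(np.mean(per_trial))
    else:
        raise ValidationError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")
    if fmvc <= 0:
        raise DegenerateCalibrationError(
            f"{cal.subject_id}/{cal.muscle}: all fMVC trials have zero amplitude; "
            "normalization impossible"
        )
    if len(per_trial) < 3:
        logger.warning(
            "%s/%s: only %d fMVC trial(s); protocol asks for at least 3",
            cal.subject_id,
            cal.muscle,
            len(per_trial),
        )
    baseline_rms = float(np.sqrt(np.mean(np.square(cal.baseline.samples))))
    return CalibrationResult(
        fmvc_value=float(fmvc),
        per_trial_values=per_trial,
        baseline_rms=baseline_rms,
        trial_count=len(per_trial),
    )


def normalize_envelope(
    envelope: RmsEnvelope,
    cal: CalibrationResult,
    subtract_baseline: bool = False,
) -> NormalizedEnvelope:
    """Express an RMS envelope in %fMVC.

    With ``subtract_baseline`` the resting RMS is removed from the raw
    envelope first (floored at zero); off by default since the protocol
    records the baseline only as a resting reference.
    """
    if not (cal.fmvc_value > 0):
        raise DegenerateCalibrationError("non-positive fMVC value; normalization impossible")
    values = envelope.values
    if subtract_baseline:
        values = np.maximum(values - cal.baseline_rms, 0.0)
    return NormalizedEnvelope(
        values=100.0 * values / cal.fmvc_value,
        window_duration=envelope.window_duration,
        step_duration=envelope.step_duration,
    )


def bandpass_filter(
    recording: EmgRecording,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    order: int = 4,
) -> EmgRecording:
    """Optional zero-phase Butterworth band-pass pre-filter.

    Disabled by default in the pipeline: the reported metrics are defined
    on the unfiltered signal, and a pre-filter is offered only for noisy
    field recordings.
    """
    nyq = recording.sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValidationError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got ({low_hz}, {high_hz})"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples)
    return EmgRecording(
        samples=filtered,
        sampling_rate=recording.sampling_rate,
        subject_id=recording.subject_id,
        group=recording.group,
        muscle=recording.muscle,
        session_kind=recording.session_kind,
    )
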