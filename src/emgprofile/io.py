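"""Recording and manifest data model plus delimited-text readers/writers.

Signal files are plain comma- or tab-delimited text with a single header
line; the delimiter is sniffed from the header.  Amplitudes are kept in
arbitrary instrument units — every downstream metric is a ratio to the
subject's fMVC, so absolute units cancel.  The reader never filters,
detrends, or rescales: what is in the file is what enters the pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError

#: The five instrumented upper-limb muscles, in report order.
MUSCLES = (
    "upper_trapezius",
    "anterior_deltoid",
    "biceps_brachii",
    "wrist_flexors",
    "wrist_extensors",
)

#: Default worker-group labels (large-herd first, the reporting convention).
GROUPS = ("large_herd_US", "small_herd_IT")

#: Metric names accepted in long-format tables.
METRICS = ("mean_rms", "apdf_p10", "apdf_p50", "apdf_p90", "percent_rest")

SESSION_KINDS = ("work", "baseline", "fmvc_trial")

_LONG_COLUMNS = ["group", "subject", "muscle", "metric", "value"]

# Column names treated as an (ignored) explicit time axis.
_TIME_NAMES = {"time", "t", "seconds", "time_s", "timestamp"}


@dataclass(frozen=True)
class EmgRecording:
    """Raw sEMG samples for one subject/muscle/session.

    Parameters
    ----------
    samples
        Amplitude values in instrument units, zero-mean expected.
    sampling_rate
        Samples per second (Hz); the field protocol records at 1000 Hz.
    session_kind
        One of ``work``, ``baseline``, ``fmvc_trial``.
    """

    samples: np.ndarray
    sampling_rate: float = 1000.0
    subject_id: str = ""
    group: str = ""
    muscle: str = ""
    session_kind: str = "work"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples contain non-finite values")
        if not (self.sampling_rate > 0):
            raise ValidationError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.session_kind not in SESSION_KINDS:
            raise ValidationError(
                f"session_kind must be one of {SESSION_KINDS}, got {self.session_kind!r}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds (sample count / sampling rate)."""
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class ManifestEntry:
    """One subject × muscle line of a cohort manifest."""

    subject_id: str
    group: str
    muscle: str
    work_path: Path
    baseline_path: Path
    fmvc_paths: tuple[Path, ...]

    def __post_init__(self) -> None:
        if len(self.fmvc_paths) < 1:
            raise ValidationError(
                f"{self.subject_id}/{self.muscle}: at least one fMVC trial path required"
            )


@dataclass
class CohortManifest:
    """Cohort description: which files belong to which subject/group/muscle."""

    entries: list[ManifestEntry]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.subject_id, e.muscle)
            if key in seen:
                raise ValidationError(f"duplicate subject×muscle entry {key}")
            seen.add(key)

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.subject_id not in out:
                out.append(e.subject_id)
        return out

    @property
    def groups(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.group not in out:
                out.append(e.group)
        return out

    @property
    def muscles(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.muscle not in out:
                out.append(e.muscle)
        return out


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ParseError(f"{path}: empty file")
    sep = _sniff_delimiter(header)
    try:
        frame = pd.read_csv(path, sep=sep)
    except Exception as exc:  # malformed text
        raise ParseError(f"{path}: could not parse delimited text ({exc})") from exc
    return frame


def read_recording(
    path: str | os.PathLike,
    column: int | str = 0,
    sampling_rate: float = 1000.0,
    *,
    subject_id: str = "",
    group: str = "",
    muscle: str = "",
    session_kind: str = "work",
) -> EmgRecording:
    """Read one channel of a delimited-text signal file.

    ``column`` selects a channel by header name or positional index
    (time-axis columns are skipped for positional selection).  An explicit
    time column, if present, is ignored after checking monotonicity.
    No resampling, filtering, or rescaling is applied.
    """
    frame = _read_table(path)
    data_cols = [c for c in frame.columns if str(c).strip().lower() not in _TIME_NAMES]
    time_cols = [c for c in frame.columns if str(c).strip().lower() in _TIME_NAMES]
    for tc in time_cols:
        tvals = pd.to_numeric(frame[tc], errors="coerce").to_numpy()
        if np.any(np.diff(tvals) < 0):
            raise ParseError(f"{path}: time column {tc!r} is not monotone non-decreasing")

    if isinstance(column, str):
        if column not in frame.columns:
            raise ValidationError(f"{path}: no column named {column!r}; columns: {list(frame.columns)}")
        name = column
    else:
        if not data_cols:
            raise ValidationError(f"{path}: no data columns")
        try:
            name = data_cols[column]
        except IndexError:
            raise ValidationError(
                f"{path}: column index {column} out of range for {len(data_cols)} data columns"
            ) from None

    values = pd.to_numeric(frame[name], errors="coerce").to_numpy(dtype=float)
    if values.size == 0:
        raise ValidationError(f"{path}: column {name!r} is empty")
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        # +2: header line plus 1-based indexing, so the index names a file row
        raise ParseError(f"{path}: non-numeric or non-finite value at data row {bad[0] + 1}")
    return EmgRecording(
        samples=values,
        sampling_rate=sampling_rate,
        subject_id=subject_id,
        group=group,
        muscle=muscle,
        session_kind=session_kind,
    )


def write_recording(recording: EmgRecording, path: str | os.PathLike, column_name: str | None = None) -> Path:
    """Write a recording as a one-column CSV (full float precision)."""
    path = Path(path)
    name = column_name or (recording.muscle or "emg")
    pd.DataFrame({name: recording.samples}).to_csv(path, index=False, float_format="%.10g")
    return path


def write_long_table(
    rows: Iterable[tuple[str, str, str, str, float]],
    path: str | os.PathLike,
) -> Path:
    """Write (group, subject, muscle, metric, value) rows as CSV.

    Metric names must come from :data:`METRICS`; column order is stable.
    """
    rows = list(rows)
    for r in rows:
        if len(r) != 5:
            raise ValidationError(f"long-table row must have 5 fields, got {r!r}")
        if r[3] not in METRICS:
            raise ValidationError(f"unknown metric name {r[3]!r}; expected one of {METRICS}")
    frame = pd.DataFrame(rows, columns=_LONG_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


def read_long_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a long-format metric table written by :func:`write_long_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metric table not found: {path}")
    frame = pd.read_csv(path, sep=_sniff_delimiter(open(path).readline()))
    missing = [c for c in _LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    unknown = set(frame["metric"]) - set(METRICS)
    if unknown:
        raise ValidationError(f"{path}: unknown metric names {sorted(unknown)}")
    return frame[_LONG_COLUMNS]


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> Path:
    """Serialize a cohort manifest to YAML with paths relative to it."""
    path = Path(path)
    base = path.parent
    doc = {
        "metadata": manifest.metadata,
        "entries": [
            {
                "subject_id": e.subject_id,
                "group": e.group,
                "muscle": e.muscle,
                "work": os.path.relpath(e.work_path, base),
                "baseline": os.path.relpath(e.baseline_path, base),
                "fmvc_trials": [os.path.relpath(p, base) for p in e.fmvc_paths],
            }
            for e in manifest.entries
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Load a YAML cohort manifest; relative paths resolve against it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ParseError(f"{path}: manifest must be a mapping with an 'entries' list")
    base = path.parent
    entries = []
    for raw in doc["entries"]:
        try:
            entries.append(
                ManifestEntry(
                    subject_id=str(raw["subject_id"]),
                    group=str(raw["group"]),
                    muscle=str(raw["muscle"]),
                    work_path=base / raw["work"],
                    baseline_path=base / raw["baseline"],
                    fmvc_paths=tuple(base / p for p in raw["fmvc_trials"]),
                )
            )
        except KeyError as exc:
            raise ParseError(f"{path}: manifest entry missing key {exc}") from exc
    return CohortManifest(entries=entries, metadata=doc.get("metadata") or {})
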