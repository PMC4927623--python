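"""End-to-end orchestration: calibrate → profile → aggregate → ANOVA.

`run_pipeline` consumes a cohort manifest, builds one activity profile
per subject/muscle, aggregates group × muscle summaries, fits the
random-block ANOVA per metric with Tukey-adjusted simple main effects,
and screens group mean profiles against the exposure limits.  A stage
failure skips that subject/muscle with a logged reason; the pipeline
fails only if no complete subject remains.  All outputs are
deterministic functions of the inputs and config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationSet, calibrate
from .errors import EmgProfileError, ModelFitError, ValidationError
from .io import (
    METRICS,
    CohortManifest,
    read_manifest,
    read_recording,
    write_long_table,
)
from .metrics import MuscleActivityProfile, ProcessingParams, build_profile, classify_exposure
from .stats import (
    AnovaResult,
    MetricDataset,
    aggregate_profiles,
    fit_random_block_anova,
    simple_main_effects,
    simple_main_effects_frame,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    adjustment: str = "tukey"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.adjustment != "tukey":
            raise ValidationError(f"only the 'tukey' adjustment is available, got {self.adjustment!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything `run_pipeline` needs, loadable from YAML."""

    manifest_path: Path
    processing: ProcessingParams = ProcessingParams()
    calibration_window: float = 3.0
    calibration_aggregate: str = "max"
    stats: StatsParams = StatsParams()
    output_dir: Path | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "manifest" not in doc:
            raise ValidationError(f"{path}: pipeline config must name a 'manifest'")
        proc = doc.get("processing") or {}
        if "percentiles" in proc:
            proc["percentiles"] = tuple(float(p) for p in proc["percentiles"])
        if proc.get("prefilter_band"):
            proc["prefilter_band"] = tuple(float(v) for v in proc["prefilter_band"])
        cal = doc.get("calibration") or {}
        st = doc.get("statistics") or {}
        out = doc.get("output_dir")
        return cls(
            manifest_path=(path.parent / doc["manifest"]).resolve(),
            processing=ProcessingParams(**proc),
            calibration_window=float(cal.get("window_duration", 3.0)),
            calibration_aggregate=str(cal.get("aggregate", "max")),
            stats=StatsParams(**st),
            output_dir=(path.parent / out).resolve() if out else None,
            log_level=str(doc.get("log_level", "INFO")),
        )

    def echo(self) -> dict:
        doc = {
            "manifest": str(self.manifest_path),
            "processing": asdict(self.processing),
            "calibration": {
                "window_duration": self.calibration_window,
                "aggregate": self.calibration_aggregate,
            },
            "statistics": asdict(self.stats),
            "log_level": self.log_level,
            "software_version": __version__,
        }
        doc["processing"]["percentiles"] = list(self.processing.percentiles)
        if self.processing.prefilter_band is not None:
            doc["processing"]["prefilter_band"] = list(self.processing.prefilter_band)
        return doc


@dataclass
class RunReport:
    """All pipeline outputs plus an audit trail of skips and warnings."""

    profiles: pd.DataFrame                       # long format, full precision
    summary: pd.DataFrame                        # group × muscle × metric mean/SD/n
    anova: dict[str, AnovaResult]
    simple_effects: dict[str, pd.DataFrame]
    exposure: pd.DataFrame
    warnings: list[str] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        """Write all report files (2-dp CSVs plus full-precision twins)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_long_table(
            list(self.profiles[["group", "subject", "muscle", "metric", "value"]].itertuples(index=False, name=None)),
            out_dir / "profiles_full.csv",
        )
        self.summary.to_csv(out_dir / "summary_full.csv", index=False, float_format="%.10g")
        self.summary.round(2).to_csv(out_dir / "summary.csv", index=False, float_format="%.2f")
        for group in self.summary["group"].unique():
            table = (
                self.summary[self.summary["group"] == group]
                .pivot(index="metric", columns="muscle", values="mean")
                .round(2)
            )
            table.to_csv(out_dir / f"summary_{group}.csv", float_format="%.2f")
        for metric, frame in self.simple_effects.items():
            frame.to_csv(out_dir / f"simple_effects_{metric}_full.csv", index=False, float_format="%.10g")
            frame.round(2).to_csv(out_dir / f"simple_effects_{metric}.csv", index=False, float_format="%.2f")
        anova_rows = []
        for metric, result in self.anova.items():
            for term in result.terms.values():
                anova_rows.append(
                    {
                        "metric": metric,
                        "term": term.name,
                        "F": term.f_value,
                        "df_num": term.df_num,
                        "df_den": term.df_den,
                        "p_value": term.p_value,
                        "sigma2_subject": result.sigma2_subject,
                        "sigma2_error": result.sigma2_error,
                    }
                )
        if anova_rows:
            pd.DataFrame(anova_rows).to_csv(out_dir / "anova.csv", index=False, float_format="%.6g")
        self.exposure.to_csv(out_dir / "exposure.csv", index=False, float_format="%.2f")
        with open(out_dir / "report.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "provenance": self.provenance,
                    "warnings": self.warnings,
                    "skipped": self.skipped,
                },
                fh,
                sort_keys=False,
            )
        return out_dir


def _entry_profile(entry, config: PipelineConfig) -> tuple[MuscleActivityProfile, list[str]]:
    warnings: list[str] = []
    work = read_recording(
        entry.work_path,
        subject_id=entry.subject_id,
        group=entry.group,
        muscle=entry.muscle,
        session_kind="work",
    )
    baseline = read_recording(
        entry.baseline_path,
        subject_id=entry.subject_id,
        group=entry.group,
        muscle=entry.muscle,
        session_kind="baseline",
    )
    trials = tuple(
        read_recording(
            p,
            subject_id=entry.subject_id,
            group=entry.group,
            muscle=entry.muscle,
            session_kind="fmvc_trial",
        )
        for p in entry.fmvc_paths
    )
    if len(trials) < 3:
        warnings.append(
            f"{entry.subject_id}/{entry.muscle}: only {len(trials)} fMVC trial(s); protocol asks for >= 3"
        )
    cal_set = CalibrationSet(
        subject_id=entry.subject_id, muscle=entry.muscle, baseline=baseline, fmvc_trials=trials
    )
    cal = calibrate(cal_set, config.calibration_window, config.calibration_aggregate)
    profile = build_profile(work, cal, config.processing)
    return profile, warnings


def run_pipeline(config: PipelineConfig, manifest: CohortManifest | None = None) -> RunReport:
    """Run the full analysis for one cohort manifest."""
    logging.getLogger("emgprofile").setLevel(config.log_level.upper())
    if manifest is None:
        manifest = read_manifest(config.manifest_path)

    rows: list[tuple[str, str, str, str, float]] = []
    warnings: list[str] = []
    skipped: list[dict] = []
    for entry in manifest.entries:
        try:
            profile, entry_warnings = _entry_profile(entry, config)
        except (EmgProfileError, OSError) as exc:
            reason = f"{type(exc).__name__}: {exc}"
            logger.warning("skipping %s/%s: %s", entry.subject_id, entry.muscle, reason)
            skipped.append({"subject": entry.subject_id, "muscle": entry.muscle, "reason": reason})
            continue
        warnings.extend(entry_warnings)
        for metric, value in profile.as_dict().items():
            rows.append((entry.group, entry.subject_id, entry.muscle, metric, value))

    if not rows:
        raise EmgProfileError("no subject/muscle entry could be processed; see skip reasons")

    profiles = pd.DataFrame(rows, columns=["group", "subject", "muscle", "metric", "value"])
    dataset = MetricDataset(
        profiles,
        group_order=tuple(manifest.groups),
        muscle_order=tuple(manifest.muscles),
    )
    summary = aggregate_profiles(dataset)

    anova: dict[str, AnovaResult] = {}
    sme: dict[str, pd.DataFrame] = {}
    for metric in METRICS:
        if metric not in set(profiles["metric"]):
            continue
        try:
            fit = fit_random_block_anova(dataset, metric, alpha=config.stats.alpha)
        except ModelFitError as exc:
            warnings.append(f"ANOVA for {metric} not fitted: {exc}")
            continue
        anova[metric] = fit
        sme[metric] = simple_main_effects_frame(simple_main_effects(fit), fit)

    exposure_rows = []
    wide = summary.pivot_table(
        index=["group", "muscle"], columns="metric", values="mean", sort=False
    )
    for (group, muscle), vals in wide.iterrows():
        profile = MuscleActivityProfile(
            mean_rms=float(vals["mean_rms"]),
            apdf_p10=float(vals["apdf_p10"]),
            apdf_p50=float(vals["apdf_p50"]),
            apdf_p90=float(vals["apdf_p90"]),
            percent_rest=float(vals["percent_rest"]),
            recording_duration=float("nan"),
        )
        assessment = classify_exposure(profile)
        exposure_rows.append(
            {
                "group": group,
                "muscle": muscle,
                "apdf_p10": profile.apdf_p10,
                "static_load": assessment.static,
                "apdf_p50": profile.apdf_p50,
                "median_load": assessment.median,
                "apdf_p90": profile.apdf_p90,
                "peak_load": assessment.peak,
            }
        )

    report = RunReport(
        profiles=profiles,
        summary=summary,
        anova=anova,
        simple_effects=sme,
        exposure=pd.DataFrame(exposure_rows),
        warnings=warnings,
        skipped=skipped,
        provenance={
            "config": config.echo(),
            "manifest_metadata": manifest.metadata,
            "n_entries": len(manifest.entries),
            "n_processed": len(manifest.entries) - len(skipped),
        },
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report
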