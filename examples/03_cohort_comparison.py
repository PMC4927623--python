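"""Simulate a two-group cohort and compare muscle activity between groups.

Generates a scaled-down synthetic cohort (6 + 6 subjects, five muscles,
60-s work recordings) with the published group × muscle mean %fMVC
levels as ground truth, runs the full pipeline, and prints the
random-block ANOVA and Tukey-adjusted simple main effects for mean RMS.
"""

import tempfile
from pathlib import Path

import emgprofile as ep

spec = ep.CohortSpec(
    groups={
        "large_herd_US": ep.GroupSpec(
            n_subjects=6,
            muscle_levels=ep.simulate.DEFAULT_GROUP_LEVELS["large_herd_US"],
            between_subject_sd=2.0,
            rest_fraction=0.13,
        ),
        "small_herd_IT": ep.GroupSpec(
            n_subjects=6,
            muscle_levels=ep.simulate.DEFAULT_GROUP_LEVELS["small_herd_IT"],
            between_subject_sd=2.0,
            rest_fraction=0.05,
        ),
    },
    work_duration=60.0,
)
config = ep.SimulationConfig(seed=5, cohort=spec)

with tempfile.TemporaryDirectory() as tmp:
    ep.simulate_cohort(config, tmp)
    report = ep.run_pipeline(ep.PipelineConfig(manifest_path=Path(tmp) / "manifest.yaml"))

fit = report.anova["mean_rms"]
print("random-block ANOVA, mean RMS (%fMVC):")
for term in fit.terms.values():
    print(
        f"  {term.name:12s} F({term.df_num:g}, {term.df_den:g}) = "
        f"{term.f_value:7.2f}   p = {term.p_value:.3g}"
    )
print()
print("simple main effects (large-herd minus small-herd), Tukey-adjusted:")
print(report.simple_effects["mean_rms"].round(3).to_string(index=False))
print()
print("The injected biceps brachii group difference is 12.47 %fMVC; the")
print("recovered delta should land near it, and muscles simulated with")
print("similar group levels should show non-significant adjusted p-values.")
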