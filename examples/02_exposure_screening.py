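"""Screen activity profiles against occupational exposure limits.

Uses the published large-herd biceps brachii profile as input and flags
its static (p10), median (p50) and peak (p90) loads against the
limit values for task durations of one hour or more:
should-not / must-not exceed 2/5, 10/14, and 50/70 %MVC respectively.
"""

import emgprofile as ep

profile = ep.MuscleActivityProfile(
    mean_rms=19.44,
    apdf_p10=1.21,
    apdf_p50=14.58,
    apdf_p90=51.22,
    percent_rest=9.45,
    recording_duration=3600.0,
)
flags = ep.classify_exposure(profile)

print("large-herd biceps brachii profile:")
for category, (p_name, value) in {
    "static": ("p10", profile.apdf_p10),
    "median": ("p50", profile.apdf_p50),
    "peak": ("p90", profile.apdf_p90),
}.items():
    should, must = ep.EXPOSURE_LIMITS[category]
    print(
        f"  {category:6s} load {p_name} = {value:5.2f} %fMVC "
        f"(limits {should}/{must}) -> {getattr(flags, category)}"
    )
print()
print("'exceeds_must_not' means the load is above the hard ceiling;")
print("'exceeds_should_not' is above the advisory limit only.")
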