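"""Profile one simulated work recording.

Builds a 10-minute synthetic sEMG recording with a known task schedule
(30 % of time in 1.5-s rest bouts, two active intensity levels), runs
the calibrate → normalize → profile pipeline, and compares the five
recovered metrics with the schedule's analytic ground truth.
"""

import numpy as np

import emgprofile as ep

config = ep.SimulationConfig(seed=1)
cycle = (
    ep.Segment("light_task", 3.5, 15.0),
    ep.Segment("rest", 1.5, 0.0),
    ep.Segment("firm_task", 3.5, 25.0),
    ep.Segment("rest", 1.5, 0.0),
)
schedule = ep.TaskSchedule(cycle * 60)  # 600 s

rng = np.random.default_rng(config.seed)
recording, truth = ep.simulate_recording(config, schedule, rng)
calibration = ep.calibrate(
    ep.simulate_calibration(config, rng, subject_id="demo", muscle="biceps_brachii")
)
profile = ep.build_profile(recording, calibration)

print(f"fMVC denominator      : {calibration.fmvc_value:.4f} (reference 1.0)")
print(f"mean RMS   (%fMVC)    : {profile.mean_rms:6.2f}   truth {truth.mean_envelope_pct:6.2f}")
print(f"APDF p10   (%fMVC)    : {profile.apdf_p10:6.2f}   truth {truth.apdf_pct[0.10]:6.2f}")
print(f"APDF p50   (%fMVC)    : {profile.apdf_p50:6.2f}   truth {truth.apdf_pct[0.50]:6.2f}")
print(f"APDF p90   (%fMVC)    : {profile.apdf_p90:6.2f}   truth {truth.apdf_pct[0.90]:6.2f}")
print(f"%MR        (% time)   : {profile.percent_rest:6.2f}   truth {truth.rest_fraction_pct:6.2f}")
print()
print("Each metric is recovered from the raw 1 kHz signal through the full")
print("pipeline; the 'truth' column is computed analytically from the schedule.")
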