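"""Monitor two days of free-living walking with a personalized model.

Simulates a two-day home recording with a ground-truth walk log, detects
walking bouts, predicts each bout's speed, applies the >= 7.62 m (25 ft)
sustained-walk and daytime gates, and prints the home summary.
"""

import gaitspeed as gs

profile = gs.make_cohort(32, seed=0)[4]

# calibrate in the clinic first
rec, walks, _ = gs.simulate_calibration_session(profile, seed=profile.seed)
uni = gs.resample_uniform(rec, rate=100.0)
model = gs.calibrate_subject(uni, [w for w in walks if w.walk_type != "free"])

# then monitor at home
home_rec, truth = gs.simulate_home_days(profile, n_days=2, seed=profile.seed)
home = gs.resample_uniform(home_rec, rate=100.0)
summary, detail = gs.monitor_recording(home, model)

fastest_truth = max(w.speed for w in truth.walks if w.distance >= 7.62)
print(f"subject {profile.subject_id}: {len(detail)} bouts detected, "
      f"{summary.n_sustained} sustained (>=7.62 m, daytime)")
print(f"max home speed : {summary.max_speed:.3f} m/s "
      f"(truth fastest sustained walk {fastest_truth:.3f} m/s)")
print(f"mean home speed: {summary.mean_speed:.3f} m/s")
print(summary.per_day.to_string(index=False))
# Max home speed should land within ~0.05 m/s of the fastest qualifying
# ground-truth walk; the per-day table mirrors the overall summary.
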