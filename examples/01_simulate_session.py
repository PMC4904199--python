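"""Simulate one testing session and look at its schedule and behaviour.

A session is one participant under one light level: 336 random-dot
trials whose 24 types (3 delays x 4 quadrants x 2 motion directions)
each appear twice in every 48-trial block.
"""

from alphalight.synth import (GeneratorParams, ScheduleConfig, SessionSpec,
                              dot_motion_speed, make_schedule,
                              simulate_session)

cfg = ScheduleConfig()
schedule = make_schedule(cfg, seed=0)
print(f"{len(schedule)} trials; "
      f"block balance: {schedule.iloc[:48].groupby(['delay_s', 'quadrant', 'direction']).size().eq(2).all()}")
print(f"coherent-dot speed: {dot_motion_speed(0.282, 21.25):.4f} deg/s")

spec = SessionSpec(participant_id="P01", light_condition="high",
                   condition_order=1, seed=42, subject_seed=7)
epochs, trials = simulate_session(spec, GeneratorParams(), schedule)
print(f"epochs: {epochs.n_trials} trials x {len(epochs.channel_labels)} "
      f"channels x {epochs.n_samples} samples at {epochs.fs:g} Hz")
means = trials.groupby("hemifield").rt_ms.mean().round(1)
print(f"mean RT by target hemifield (ms):\n{means}")
# Under high light the generator speeds left-hemifield responses only;
# the ground-truth alpha columns (log_alpha_true_*) let recovery tests
# check every downstream stage.
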