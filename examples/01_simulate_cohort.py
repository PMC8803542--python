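"""Simulate the task schedule, a crossover cohort, and one BOLD session.

The schedule alternates 8 move and 8 rest blocks of 20 s (320 s total)
with 7 jittered auditory cues per move block.  The cohort gives every
subject all six polarity-by-time sessions; post sessions of the listed
polarities carry additive coupling shifts (the ground truth that later
stages try to recover).
"""

import numpy as np

from motordcm import (generate_schedule, CohortSpec, GroundTruthEffects,
                      simulate_session_bold)
from motordcm.synth import generate_cohort, session_model

schedule = generate_schedule(seed=1)
print(f"blocks: {len(schedule.block_onsets)} "
      f"({sum(t == 'move' for t in schedule.block_types)} move), "
      f"cues: {len(schedule.cue_onsets)}, duration: {schedule.total_duration} s")

effects = GroundTruthEffects.default("exp2")   # cerebellar-montage pattern
cohort = generate_cohort(CohortSpec(n_subjects=21, seed=1), effects)
print(f"cohort: {cohort['n_subjects']} subjects, "
      f"{cohort['n_sessions']} sessions")

pre = session_model(cohort, 0, "cathodal", "pre")
post = session_model(cohort, 0, "cathodal", "post")
print(f"injected thalamus->M1 shift (cathodal post - pre): "
      f"{post.a_off[0, 2] - pre.a_off[0, 2]:+.2f} Hz")

run = simulate_session_bold(pre, schedule, TR=2.7, noise_sd=0.1,
                            relative_noise=True, seed=7)
print(f"simulated run: {run.n_volumes} volumes x {len(run.regions)} regions "
      f"(TR {run.TR} s); signal sd per region: "
      f"{np.round(run.ground_truth.std(axis=0), 4)}")
# The 119-volume, TR 2.7 s run covers the 320 s task; the printed shift is
# the polarity-by-time effect the group analysis should detect.
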