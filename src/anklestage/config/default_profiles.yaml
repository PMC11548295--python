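# Per-stage feature distributions used by the synthetic session generator.
#
# One entry per Brunnstrom stage I-V.  Means are chosen to be well separated
# and clinically ordered: active range of motion (radians), voluntary angular
# speed (rad/s, stage V at the pi/6 nominal guidance speed), movement jerk
# (rad/s^3, high = poor motor control, so it decreases with recovery), the
# normalized assessment score in [0,1], the expected per-session task
# completion count, and the mean task completion degree in [0,1].
profiles:
  - stage: I
    arom_mean: 0.15
    arom_sd: 0.030
    angvel_mean: 0.10
    angvel_sd: 0.020
    jerk_mean: 80.0
    jerk_sd: 12.0
    eval_score_mean: 0.15
    eval_score_sd: 0.05
    tc_rate: 2.0
    completion_mean: 0.20
    completion_sd: 0.06
  - stage: II
    arom_mean: 0.30
    arom_sd: 0.035
    angvel_mean: 0.20
    angvel_sd: 0.025
    jerk_mean: 60.0
    jerk_sd: 10.0
    eval_score_mean: 0.35
    eval_score_sd: 0.05
    tc_rate: 4.0
    completion_mean: 0.40
    completion_sd: 0.06
  - stage: III
    arom_mean: 0.45
    arom_sd: 0.040
    angvel_mean: 0.30
    angvel_sd: 0.030
    jerk_mean: 40.0
    jerk_sd: 8.0
    eval_score_mean: 0.55
    eval_score_sd: 0.05
    tc_rate: 6.0
    completion_mean: 0.60
    completion_sd: 0.06
  - stage: IV
    arom_mean: 0.60
    arom_sd: 0.045
    angvel_mean: 0.42
    angvel_sd: 0.030
    jerk_mean: 25.0
    jerk_sd: 6.0
    eval_score_mean: 0.75
    eval_score_sd: 0.05
    tc_rate: 8.0
    completion_mean: 0.75
    completion_sd: 0.05
  - stage: V
    arom_mean: 0.75
    arom_sd: 0.050
    angvel_mean: 0.5235987755982988   # pi/6, the nominal voluntary speed
    angvel_sd: 0.030
    jerk_mean: 15.0
    jerk_sd: 4.0
    eval_score_mean: 0.90
    eval_score_sd: 0.04
    tc_rate: 10.0
    completion_mean: 0.90
    completion_sd: 0.04
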