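"""Run one closed-loop position-control trial and summarize it.

The synthetic user lifts the arm by contracting the abduction pattern; every
25 ms the decoder classifies the preceding 200 ms of EMG and the controller
converts (class, PC) into a vertical velocity command.  The trial prints the
decision mix, whether the arm entered the 80-100 degree target window, the
in-window reach metrics, and the sensed force while reaching (negative =
the user pressing down on the rigid support, as a stroke survivor engaging
the extensor synergy does).
"""

from collections import Counter

import numpy as np

from myoarm import SubjectProfile, excursion_metrics, simulate_session

profile = SubjectProfile()  # k_syn = 0.6: moderate abnormal synergy
trial = simulate_session(profile, "position", n_trials=1, seed=4)[0]

mix = Counter(d.class_label for d in trial.decisions)
print(f"decisions: {dict(mix)} over {len(trial.decisions)} windows")
print(f"abduction range covered: {trial.theta_abd.min():.1f} - "
      f"{trial.theta_abd.max():.1f} deg (window is 80-100)")

m = excursion_metrics(trial)
print(f"in-window elbow flexion minimum: {m.elbow_deg:.1f} deg "
      "(smaller = more extension)")
print(f"in-window horizontal adduction maximum: {m.shoulder_deg:.1f} deg "
      "(larger = further reach)")

in_win = (trial.theta_abd >= 80) & (trial.theta_abd <= 100)
print(f"mean sensed force while in-window: {trial.F_sensed[in_win].mean():.1f} N "
      "(negative: bearing down on the rigid support)")
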