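"""Fit the 3-class decoder from the calibration protocol and score it.

Generates the position-controller training protocol (23 ten-second trials:
3 postures x 2 repetitions x 3 classes, plus 5 supported-reach trials
labeled no-movement), trains the minimum-Mahalanobis model, and classifies
fresh held-out trials.  Also shows how the proportional-control magnitude
scales with contraction intensity.
"""

import numpy as np

from myoarm import (SubjectProfile, build_training_protocol, classify,
                    generate_class_emg)
from myoarm.pipeline import featurize_recording, train_from_recordings

profile = SubjectProfile()
protocol = build_training_protocol(profile, "position", seed=0)
model = train_from_recordings(protocol)
print(f"trained on {len(protocol)} trials "
      f"({sum(r.label == 'no_movement' for r in protocol)} no-movement)")

for klass in model.classes:
    rec = generate_class_emg(profile, klass, duration_s=5.0, seed=123)
    labels = [classify(fv, model).class_label
              for fv in featurize_recording(rec, model.thresholds)]
    acc = 100.0 * np.mean([l == klass for l in labels])
    print(f"held-out {klass:<12s} window accuracy: {acc:5.1f} %")

# PC grows quadratically with contraction intensity: a gentle abduction
# nudges the support, a strong one moves it fast.  Contractions well below
# the training level fall back to no-movement — the decoder ignores them.
for intensity in (0.5, 0.75, 1.0):
    rec = generate_class_emg(profile, "abduction", intensity=intensity,
                             duration_s=2.0, seed=9)
    ds = [classify(fv, model)
          for fv in featurize_recording(rec, model.thresholds)]
    abd = [d.pc for d in ds if d.class_label == "abduction"]
    frac = 100.0 * len(abd) / len(ds)
    pc = np.median(abd) if abd else float("nan")
    print(f"intensity {intensity:.2f} -> {frac:5.1f} % abduction windows, "
          f"median PC {pc:.3f}")
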