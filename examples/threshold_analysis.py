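"""Operating-point analysis of a score set on a 20/80 benchmark shape.

Generates binormal scores calibrated to AUC 0.944 over 20 positives and 80
negatives (the composition of a public dermoscopic benchmark), then prints
the SEN-target threshold sweep, the balanced operating point, and how many
of the packaged dermatologist reader groups fall below the ROC curve.
"""

from dermbalance import (
    balanced_threshold,
    generate_scores,
    reader_points,
    readers_outperformed,
    roc_and_auc,
    threshold_sweep,
)

scores, labels = generate_scores(20, 80, auc_target=0.944, seed=1)
curve = roc_and_auc(scores, labels)
print(f"AUC: {curve.auc:.3f}\n")

print("SEN target -> operating point (largest threshold with SEN >= target)")
for row in threshold_sweep(scores, labels, sen_targets=(1.0, 0.95, 0.90, 0.85, 0.80)):
    p = row["point"]
    print(f"  SEN >= {row['target']:.2f}: threshold {p.threshold:.5f} "
          f"SEN {p.sen:.3f} SPE {p.spe:.3f}")

point = balanced_threshold(scores, labels, criterion="min_gap")
print(f"\nbalanced point (min |SEN-SPE|): threshold {point.threshold:.5f} "
      f"SEN {point.sen:.3f} SPE {point.spe:.3f}")

n_out, flags = readers_outperformed(curve, reader_points())
print(f"\nreader groups strictly below the curve: {n_out} of {len(flags)}")
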