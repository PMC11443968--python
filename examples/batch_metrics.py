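"""A small simulation campaign and its behavioral summary.

Simulates two calibrated driver pairs over three kinematic conditions with
noise enabled, then aggregates the three behavioral levels per condition:
safety margin (mean merge gap), high-level outcome (probability the left
driver merges first, with a binomial CI), and collision counts.
"""

import ceimerge as cm

pairs = [(cm.make_thresholds(3, "left"), cm.make_thresholds(3, "right")),
         (cm.make_thresholds(6, "left"), cm.make_thresholds(6, "right"))]
conditions = [cm.Condition.from_label(lbl) for lbl in ("-4_0", "0_0", "4_0")]

records = cm.run_batch(pairs, conditions, repetitions=5, base_seed=7)
summary = cm.batch_summary(records, group_by="condition")

print(summary[["condition", "n", "n_collisions", "mean_gap",
               "p_left_first", "p_left_first_ci_low",
               "p_left_first_ci_high"]].to_string(index=False,
                                                  float_format="%.2f"))
print("\nA positive projected headway favours the left driver: its")
print("probability of merging first rises from -4_0 to 4_0, while the")
print("realised safety margin stays within a narrow band across conditions.")
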