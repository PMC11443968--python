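"""One dyadic merging trial, step by step.

Runs the most asymmetric calibrated driver pair (pair 3: left upper threshold
0.488, right 0.631) in the fully symmetric condition 0_0 — equal speeds,
equal projected positions — without noise, and prints every replanning event
and the trial outcome. The driver with the lower risk tolerance acts; the
other barely does.
"""

import ceimerge as cm

pair = (cm.make_thresholds(3, "left"), cm.make_thresholds(3, "right"))
record = cm.run_trial("0_0", pair, noise=False)

print(f"condition {record.condition_label}, noise off")
for side in ("left", "right"):
    trace = record.trace(side)
    print(f"\n{side} driver (theta_u = {pair[side == 'right'].theta_u}):")
    for t, event, a in zip(record.t, trace.event, trace.a_input):
        if event != "none":
            print(f"  t = {t:5.2f} s  {event:<10s} -> input {a:+.2f} m/s^2")

out = record.outcome
print(f"\noutcome: {'collision' if out['collision'] else 'no collision'}, "
      f"{out['who_first']} merged first, "
      f"gap at merge {out['merge_gap']:.2f} m, duration {out['duration']:.1f} s")
print("\nThe left driver's lower upper threshold trips first ('upper' event):")
print("it brakes to push the perceived collision probability below 0.8 x rho_l,")
print("then relaxes back to its preferred speed once risk stays low for tau s.")
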