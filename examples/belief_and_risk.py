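"""Anatomy of the risk signal: from observation to thresholds.

Builds one driver's view of an approaching vehicle by hand — perceived
velocity, acceleration memory, the projected Gaussian-mixture belief — then
evaluates the collision probability of a constant-speed plan against that
belief and the dynamic risk thresholds it is compared with.
"""

import ceimerge as cm
from ceimerge.perception import AccelerationMemory
from ceimerge.risk import plan_positions_risk

params = cm.SimParams()
geometry = cm.TrackGeometry()

# the other vehicle: observed 30 m behind the merge point, braking lately
memory = AccelerationMemory(params.memory_size)
for a in [0.0] * 60 + [-0.5] * 20:
    memory.append(a)
obs = cm.PerceptionState(v_perceived=10.2, observed_position=70.0)
belief = cm.project_belief(obs, memory, params)

mu_a, var_a = cm.expected_acceleration(memory, params.ac)
print(f"expected acceleration: mean {mu_a:+.3f} m/s^2, sd {var_a**0.5:.3f}")
print("belief points (every 1 s of the 6 s horizon):")
for k in range(3, 24, 4):
    print(f"  t+{belief.offsets[k]:.2f} s: mu {belief.mus[k]:7.2f} m, "
          f"sigma {belief.sigmas[k]:5.2f} m")

# ego plan: hold 10 m/s from 72 m — slightly ahead, converging paths
offsets = belief.offsets
ego_positions = 72.0 + 10.0 * offsets
risk = float(plan_positions_risk(ego_positions, belief, geometry))
print(f"\nperceived collision probability of the plan: {risk:.3f}")

thresholds = cm.make_thresholds(3, "left")
rho_l, rho_u = cm.dynamic_thresholds(thresholds, delta_p=2.0, delta_v=-0.2)
print(f"dynamic thresholds at dp=+2 m, dv=-0.2 m/s: "
      f"rho_l {rho_l:.3f}, rho_u {rho_u:.3f}")
verdict = ("replan (risk above rho_u)" if risk > rho_u else
           "keep the current plan")
print(f"-> {verdict}")
print("\nThe belief widens quadratically with lead time and with the")
print("inconsistency of recently observed accelerations; risk is the")
print("mixture mass inside the collision bounds around the planned path.")
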