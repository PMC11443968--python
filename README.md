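# ceimerge

A computational model of how two human drivers resolve a merging conflict —
and a laboratory for studying the communication loop between them.

Two vehicles approach a single merge point on separate roads. Neither driver
can steer; each only controls acceleration, wants to keep their initial
velocity, and must not collide. `ceimerge` simulates this dyad with a
communication-enabled interaction (CEI) model: each driver holds a
deterministic *plan*, forms a probabilistic *belief* about the other
vehicle's future positions from its observed kinematics, perceives *risk* as
the believed collision probability, and *replans intermittently* when that
risk crosses personal thresholds. The package is for researchers in driver
modelling, human factors, and interaction-aware automated driving who want a
fully reproducible, parameterised implementation of the model, its behavioral
metrics, and its calibration procedure.

## The model in brief

**Plan.** A driver holds a single constant acceleration input `a` chosen by
minimising, over a horizon `T`,

    J(a) = Σ_t (v_t − v_d)² + a²,

subject to the perceived collision risk of the resulting trajectory staying
below a cap — safety is a satisficing constraint, not a cost term. The
executed input is the planned one plus motor noise, drawn once per replan and
frozen. When no feasible input exists, the driver falls back to full braking
(if behind) or full acceleration (if ahead).

**Communication and belief.** Position and acceleration of the other vehicle
are observed perfectly; velocity is perceived through leaky evidence
accumulation, `v_p ← v_p + α (v_r − v_p) + β dW`. From a `T_m`-second memory
of observed accelerations with mean `μ_a` and variance `var(M)`, the driver
projects, for each future time `t`, a two-component Gaussian mixture over the
other vehicle's position:

    b_t = ½ N(μ_t, σ_t²) + ½ N(μ_t, φσ_t²),
    μ_t = p + v_p (t−t₀) + ½ μ_a (t−t₀)²,
    σ_t = ½ (t−t₀)² σ_a,      σ_a² = (a_c/3)² + var(M).

The wide component reserves probability for unexpected manoeuvres;
inconsistent recent behaviour widens both.

**Risk and thresholds.** Risk is the maximum, over belief points, of the
mixture mass inside the interval of other-vehicle positions that would
overlap the ego's planned position (possible only within a vehicle length of
the merge point). It is compared against dynamic thresholds

    ρ_u = θ_u + λ_u·(Δp, Δv, ΔpΔv),    ρ_l = θ_l + λ_l·(Δp, Δv, ΔpΔv),

personal base values plus a population-level incentive shift in the relative
position and velocity from the driver's perspective. Exceeding ρ_u triggers
an evasive replan (risk capped at 0.8 ρ_l); staying below ρ_l for the
saturation time τ triggers a recovery replan (cap 0.6 ρ_u); crossing the
desired velocity triggers a speed-holding replan.

**Calibration.** Because control is intermittent, thresholds are estimated by
grid search: a 25×25 grid of (θ_l, θ_u) is simulated per condition (one model
driver vs. a constant-velocity opponent, noise off), each observed trial is
matched to the grid cell whose velocity deviation at 1.0 s best agrees, and
two linear mixed-effects models (`θ ~ Δp * Δv`, random intercept per
participant) pool the matched values into per-participant base thresholds and
population incentive coefficients.

## A worked example

```python
import ceimerge as cm

pair = (cm.make_thresholds(3, "left"), cm.make_thresholds(3, "right"))
record = cm.run_trial("0_0", pair, noise=False)
print(record.outcome)
```

prints

```
{'collision': False, 'duration': 16.75, 'merge_gap': 1.8790771655838938,
 'who_first': 'right'}
```

Pair 3 is strongly asymmetric (left θ_u = 0.488, right θ_u = 0.631). In the
perfectly symmetric condition `0_0` the left driver's threshold trips first
(an `upper` event at t = 5.10 s, right after the tunnel exit at 5.05 s); it
brakes, yields, and the right driver merges first with a 1.88 m
bumper-to-bumper clearance at the merge point. The scripts in `examples/`
walk through a single trial, a small campaign with per-condition metrics, the
anatomy of the belief/risk signal, and a calibration parameter-recovery run.

Condition labels follow the convention `<projected headway>_<relative
velocity × 10>`: `"4_-8"` means the left driver projects 4 m ahead at the
merge point but is 0.8 m/s slower.

## Layout

| module | contents |
| --- | --- |
| `ceimerge.scenario` | track geometry, point-mass dynamics with resistance, conditions |
| `ceimerge.perception` | velocity evidence accumulation, acceleration memory, belief |
| `ceimerge.planner` | constrained constant-acceleration planner, fallback, motor noise |
| `ceimerge.risk` | collision bounds, perceived risk, dynamic thresholds |
| `ceimerge.simulation` | per-driver replanning state machine, trial/batch loops, CSV export |
| `ceimerge.metrics` | merge gap, merge order, velocity-deviation statistics |
| `ceimerge.calibration` | threshold grid search, trial matching, mixed-effects pooling |
| `ceimerge.defaults` | calibrated per-driver thresholds and incentive coefficients |

See `docs/methods.md` for the full model description, parameter table, and
known limitations.
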