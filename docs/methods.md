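# Methods

This note documents the model implemented by `ceimerge`, the choices made
where the design was genuinely open, and what the tests do and do not
establish.

## Scenario

Two point-mass vehicles (4.5 m × 1.8 m, dimensions used only for collision
detection) travel along a 150 m track of three 50 m sections: a tunnel, an
approach, and a follow section. The two approach roads join at the merge
point (100 m). Inside the tunnel a driver has no control authority and the
velocity is held exactly constant; control begins when the own front bumper
passes the tunnel exit. Outside the tunnel the dynamics are semi-implicit
Euler at dt = 0.05 s with a velocity-dependent resistance
`a_r = 0.5 + 0.005 v²` and a hard floor at v = 0.

A *condition* fixes the projected front-to-front headway at the merge point
under constant initial velocities, and the initial relative velocity
(positive = advantage for the left driver). Initial speeds are 10/10 m/s or
10.4/9.6 m/s. The slower (or disadvantaged) vehicle starts at s = 0; the
other vehicle's start offset is solved from the first-arrival headway
constraint and may be negative (the tunnel is conceptually extended
backwards). This is the unique placement family that makes left/right
mirroring an exact symmetry of the simulation, which the tests verify
bitwise. The default design holds 11 conditions: all five headways
{−4, −2, 0, 2, 4} m at equal speeds, and headways {−4, 0, 4} m at ±0.8 m/s.
Which 11 of the 15 possible cells constituted the original design is not
documented; this subset is an assumption and is config-overridable.
Collisions are detected with a shared-corridor rule: both fronts within one
vehicle length past `merge − L` and front-to-front distance below L. A trial
ends when both front bumpers pass the track end, on collision, or at a 60 s
safety cap.

## Driver model

Each driver runs four coupled processes per 0.05 s step.

**Perception.** The other vehicle's position and acceleration are observed
perfectly; its velocity through leaky evidence accumulation
`v_p ← v_p + α (v_r − v_p) + β dW`, `dW ~ N(0, dt)`. With the defaults
(α = 0.5, β = 0.6) the stationary error sd is
`β √(dt / (1 − (1−α)²)) ≈ 0.155 m/s` — enough to flip which driver perceives
an advantage in symmetric conditions, which is the model's source of
accelerate-vs-brake variability. The perceived velocity is initialised at the
true value; the ~5 s tunnel lets the stationary noise develop before control
begins.

**Belief.** A ring buffer holds the last Tm = 4 s of observed accelerations
(seeded with one zero entry at trial start; before 4 s of history exists, all
available observations are used). With mean μ_a and *population* variance
var(M), the expected acceleration is `N(μ_a, σ_a²)`,
`σ_a² = (a_c/3)² + var(M)`. Belief points at 4 Hz over the 6 s horizon (the
current instant excluded — it carries no planning-relevant collision
information) are two-component Gaussian mixtures with

    μ_t = p + v_p (t−t₀) + ½ μ_a (t−t₀)²,
    σ_t = ½ (t−t₀)² σ_a  (default),

mixture weights ½/½ and the wide component's variance scaled by φ = 3. The
printed source equation for the spread reads as a variance
(`σ_t² = ½ (t−t₀)² σ_a²`); that alternative is available via
`SimParams(belief_sigma_mode="variance")`. The default follows exact Gaussian
propagation of an uncertain constant acceleration, and is also the reading
that reproduces the published batch behavior — under the variance reading the
simulated drivers keep ~2.2 m mean gaps and never collide, far from the
reported values.

**Risk.** For each belief point, the collision bounds around the planned ego
position x are `(max(x − L, merge − L), x + L)`, empty while the planned
position is more than a vehicle length before the merge point. The perceived
risk is the **maximum** over belief points of the mixture mass inside the
bounds. The per-point→scalar aggregation rule is not documented in the
source; maximum is conservative, scale-free, and keeps risk in [0, 1]. A
"sum capped at 1" variant is selectable (`risk_aggregation="sum"`) but makes
the replanning caps practically unsatisfiable — drivers stall in permanent
fallback — so it is ruled out as the operative rule.

Risk is evaluated against the **frozen planned trajectory**, not a rollout
from the current state: between replans, execution-noise drift goes unnoticed
by the driver. This is deliberate (the driver evaluates the plan they believe
they are executing) and materially matters: re-anchoring the evaluation to
the true state each step almost eliminates collisions (1/990 vs ~37/990).
Plans are rolled out over 2T so they cover the belief horizon between
replans; a plan older than T (rare — recovery replans refresh plans every
~τ s) saturates at its final waypoint.

**Thresholds and replanning.** The dynamic thresholds are
`ρ = θ + λ₁Δp + λ₂Δv + λ₃ΔpΔv` per driver perspective, with Δp the
front-bumper position difference and Δv using the perceived other-velocity.
The incentive inputs are clamped to the domain the coefficients were
calibrated on (Δp ∈ [−4, 4] m, Δv ∈ [−0.8, 0.8] m/s). Without this clamp the
linear terms explode once the conflict resolves and the vehicles separate
(|Δp| grows without bound), pinning both thresholds at their guards and
leaving drivers unable to trigger any further replan — they then crawl or run
away indefinitely. Outputs are additionally clamped to (0, 1) with
ρ_l < ρ_u enforced.

Triggers, in priority order: (i) risk > ρ_u → evasive replan with cap
0.8 ρ_l; (ii) risk < ρ_l continuously for τ = 1.6 s → recovery replan with
cap 0.6 ρ_u (the timer clears whenever risk ≥ ρ_l and after the replan);
(iii) the velocity crosses the desired velocity while a nonzero input is
applied → speed-holding replan. The crossing trigger is edge-triggered (sign
change of v − v_d, or entry into a 0.01 m/s band): a level-triggered reading
would refire every step near v_d and destroy the intermittent control the
model exists to produce. The speed-holding replan and the initial plan at
control onset are unconstrained (cap 1); no cap is documented for them, and
an overly risky outcome is corrected by trigger (i) at the next step.
Infeasible replans fall back to full braking (behind; ties brake) or full
acceleration (ahead), retrying the optimisation each step.

**Planner.** The 1-D constrained problem — minimise
`Σ (v_k − v_d)² + Σ a²` over constant a ∈ [−2, 2] m/s² subject to the risk
cap — is solved on a 1 mm/s² lattice: a 201-point coarse scan, then fine
scans around the best feasible cell and around every feasibility boundary,
with a full lattice sweep before declaring infeasibility. A lattice scan
(rather than, e.g., golden-section refinement) keeps the solver deterministic
and exactly reproducible against a brute-force oracle, which the tests
enforce on randomized constrained instances (agreement ≤ 1e−3 m/s²). The
cost rollout includes resistance by default (the executed dynamics do, so the
driver's internal model matches); consequently the unconstrained optimum at
v = v_d is a small positive input strictly below the drag, and an undisturbed
driver drifts ~0.1 m/s below its desired speed per second of horizon — the
"passive" response is a small negative deviation, not exactly zero.

**Execution noise.** The printed noise scale (σ_n = 140) cannot be m/s²; the
adopted mapping is σ_n/1000 = 0.14 m/s² (reading it as mm/s²), isolated in
`noise_sd_from_sigma_n`. One draw per replan, frozen until the next replan,
applied to the executed input only (never to the planned trajectory used for
risk).

## Fixed parameters

| parameter | value | meaning |
| --- | --- | --- |
| dt | 0.05 s | simulation step |
| T | 6.0 s | planning and belief horizon |
| Tm | 4.0 s | acceleration-memory span |
| fb | 4 Hz | belief-point frequency (24 points) |
| σ_n | 140 (→ 0.14 m/s²) | execution-noise scale |
| β | 0.6 | velocity-perception noise level |
| τ | 1.6 s | saturation time for the recovery trigger |
| φ | 3.0 | wide-component variance scaling |
| α | 0.5 | perception update rate |
| a_c | 1.0 m/s² | comfortable acceleration (belief baseline) |
| a_max | 2.0 m/s² | control bound (undocumented in the source; exposed) |

Per-driver base thresholds for the nine calibrated pairs and the population
incentive coefficients λ_u = (0.003, 0.018, −0.006),
λ_l = (0.004, 0.016, −0.003) ship in `ceimerge.defaults`.

## Calibration pipeline

`build_grid` spans θ_u ∈ [0.3, 0.9] and θ_l ∈ [0.01, 0.4] with 25 points per
axis (625 cells; cells with θ_l ≥ θ_u are carried but not simulable).
`grid_response_lookup` simulates, per cell and condition, one deterministic
trial of a single model driver against a constant-velocity opponent
(incentives and all noise off) and records the signed velocity deviation
1.0 s after control onset. `match_trial_thresholds` returns the cell with the
closest deviation; ties break to the most passive cell (largest θ_u, then
θ_l), the unique order-stable representative — zero-ish deviations are
consistent with any sufficiently high threshold. Signed matching is the
default (braking and accelerating responses distinguish cells);
absolute-value matching is selectable. `fit_incentive` pools trial-level
estimates with statsmodels MixedLM (`θ ~ Δp * Δv`, random intercept per
participant, REML): fixed slopes become λ, intercept plus random effects the
per-participant θ. Condition covariates enter from each driver's perspective
(sign-flipped for right-side drivers).

**Identifiability.** The grid response is piecewise constant in θ_u: all
cells whose threshold lies below the onset risk trigger identically, and all
cells that never trigger within 1.0 s share the passive drift response.
Within such plateaus, thresholds are indistinguishable *in principle* and the
most-passive tie-break maps the whole plateau to its top — per-trial
recovery is exact only up to response equivalence, and pooled estimates are
biased upward while preserving participant ordering (the recovery tests
check: one-grid-step accuracy wherever the response is informative and
unique, response-equivalence otherwise, and rank correlation ≥ 0.9 for the
pooled intercepts on the calibrated threshold set).

## Synthetic participants

`synth_participants` emulates the trial-level observations the fitting
procedure consumes: each synthetic participant is a model driver with known
thresholds facing a constant-velocity opponent, per condition × repetition,
alternating left/right sides as in a paired experiment. Noise is off by
default (repetitions are identical, as the recovery tests require); enabling
it adds perception and execution noise, emulating response variability but
not any other feature of human data — no per-trial attention lapses, no
learning across repetitions, no asymmetric braking preference. A green
recovery test therefore establishes that the pipeline inverts the model's
own forward map, not that it recovers human thresholds.

## Batch-level replication

With all defaults (nine calibrated pairs, 11 conditions, 10 repetitions,
seed 1), `scripts/acceptance.py` computes a mean merge gap of **4.15 m**
(bumper-to-bumper clearance at the instant the trailing vehicle's front
crosses the merge point, interpolated between steps, collisions excluded)
and **37/990** collision trials; across seeds these vary by ~±0.1 m and ±2.
The collision count sits inside the published band. The mean gap falls
~0.6 m short of the published model value (4.8 m). The shortfall is robust to
every documented reading we could vary — gap-measurement instant (leading
crossing gives 2.4 m, trailing 4.15 m), belief-spread reading, risk
aggregation — and a sensitivity sweep over the unrecoverable execution-noise
scale shows gap and collision count rising together (0.28 m/s² noise gives
5.3 m but 58 collisions), so no scale reproduces both published values
simultaneously. Likely residual causes: the unknown true σ_n scaling, the
assumed 11-condition subset, and the undocumented a_max.

## Known limitations

- One spatial dimension: no steering, lateral dynamics, or right-of-way.
- Beliefs are unimodal in intent: a single constant-acceleration prediction,
  no manoeuvre-level hypotheses.
- The incentive function is linear and shared across drivers; its inputs are
  clamped to the calibrated domain (see above).
- The grid-search calibration inherits the intermittency problem it was
  designed around: trials where the threshold never trips are uninformative,
  and response plateaus bound the achievable resolution.
- The 20 s post-collision pause of the original experiment is not simulated;
  a collision simply ends the trial.
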