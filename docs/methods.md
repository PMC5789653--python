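# Methods

## Feedback loops and equilibria

A regulated parameter `P` and its controlling hormone `H` form a negative
loop with two strictly monotone arms. The sensor arm is log-linear,
`H = exp(α ± βP)` with `β > 0`: hormone output stays strictly positive for
any parameter level, and the log-linear shape follows the convention
established for the TSH–FT4 relationship. The effector arm is a saturating
hyperbola, `P = P0 + G·H/(H+K)` (stimulatory) or `P = P0 + G·K/(H+K)`
(suppressive): parameter output is physiologically bounded between a basal
level `P0 ≥ 0` and a ceiling `P0 + G`, with half-activation at `H = K`.
Nothing in the sign analysis depends on these particular shapes — any pair
of strictly monotone curves with opposite directions gives the same
conclusions — and both types are small, replaceable value objects. Units
are abstract throughout; there is no unit-conversion layer.

Because one arm is stimulatory and the other suppressive, the composition
`P ↦ g(f(P))` is strictly decreasing, maps `[P0, P0+G]` into itself, and
has exactly one fixed point. `solve_equilibrium` brackets it on
`[P0, P0+G]` and applies Brent's method (tolerance default 1e-9 parameter
units, iteration cap 200); if the residual `|g(f(P*)) − P*|` still exceeds
the tolerance (a very steep composition), plain bisection refines the
surviving bracket until it does not. Degenerate curves (`β = 0` or
`G = 0`) are rejected at construction rather than handled downstream. The
cohort simulator solves all individuals at once with a fixed-count
vectorized bisection over the same bracket; a test pins its agreement with
the scalar solver.

Three predefined systems fix the arm directions: calcium/PTH (sensor
suppressive, effector stimulatory), glucose/insulin (sensor stimulatory,
effector suppressive), FT4/TSH (like calcium/PTH). Their template
parameters (`α = ±1`, `β = 1`, `P0 = 0.5`, `G = 1`, `K = 1`) are chosen so
the template equilibrium is exactly `(P*, H*) = (1, 1)` — a convenient
anchor in abstract units; only correlation signs, never magnitudes, are
claims.

## Population simulators

`PopulationSpec` describes one synthetic cohort. Curve parameters vary
across individuals log-normally with median equal to the template value:
`draw = template · exp(σZ)`, `σ² = ln(1 + CV²)`, so the draw mean is
`template · exp(σ²/2)` (within 2% of the template at CV 0.2). Draws are
independent across parameters and individuals from a single generator
seeded per cohort; the seed and all drawn parameters are kept in the sample
for audit. Log-normal was chosen for positive support and natural CV
parameterization; the sign results are insensitive to the family.

Variation modes: `effector_dominant` (sensor CVs forced to zero — the
default, reflecting that homeostasis is best served by a tightly conserved
hormone response to the parameter, which is what restricts the range of
equilibria and produces the empirical sign), `sensor_dominant`, and
`mixed`. Default CVs are 0.2 on the effector parameters and 0.1 on the
set-point target.

*Equilibrium cohorts*: each individual's `(P, H)` is their solved fixed
point. In effector-dominant mode every point lies on the shared sensor
curve, so Spearman's ρ is exactly ±1 with the sensor's sign — a
construction, not a statistical tendency. As sensor variation grows
(`mixed` mode) the correlation degrades continuously toward zero; a test
checks this convergence on a CV grid.

*Set-point cohorts*: each individual receives a target `T` from a normal
distribution (mean defaulting to the template equilibrium `P* = 1`, CV
0.1) truncated to their own invertible range `(P0 + εG, P0 + (1−ε)G)`,
`ε = 0.05`, and attains it exactly through the closed-form effector
inverse `H = g⁻¹(T)`. Truncation is exact inverse-CDF sampling of the
per-individual truncated normal — rejection sampling would fail for tail
individuals whose range holds little target mass; a guard raises if an
individual's range holds essentially none (< 1e-12). Targets are drawn
independently of the effector parameters, encoding the set-point premise
that targets are chosen without regard to effector sensitivity. The
controller is modeled as exact steady-state attainment, not a dynamic PI
loop: only steady states are compared.

What the generator emulates: cohorts of healthy individuals in the normal
range whose paired parameter/hormone levels arise from one of the two
regulation models. What it does not emulate: assay noise, within-individual
longitudinal variation, pulsatile secretion, subpopulation structure, or
any calibration to real concentration scales. Passing sign tests therefore
show that each model *forces* its correlation sign under inter-individual
variation — they do not validate the curve shapes against real cohorts.

## Correlation analysis

`correlation` wraps Pearson/Spearman (two-sided p-values from the t
transform with n−2 df, resp. the large-sample approximation) and refuses
zero-variance input. `implied_sign` encodes the two predictions: set-point
→ effector direction; equilibrium (effector-dominant) → sensor direction.
These are opposite for every negative loop, so no record can be consistent
with both — a property test.

Records are classified by the sign of the printed point estimate;
significance labels are carried through but never alter classification
(non-significant rows count), and an exact zero is indeterminate, never
coerced. The packaged table of ten published cohort correlations stores
per-row sample sizes as printed (486, 460, 35, 35, 45, 148, 142, 3640,
3434, 3247), flags the three rows computed on log-transformed insulin, and
keeps source labels free-text. The two aggregate study sizes quoted
elsewhere for the calcium/PTH studies are read as 946 (= 486 + 460) and
115 (= 35 + 35 + 45), consistent with the per-row values.

## Heating analogy

A radiator house has four elements that switch on when the temperature
drops strictly below 22/20/18/16 °C (at exactly the threshold an element is
off; there is no hysteresis — activation is a pure function of the current
temperature). Steady state solves `p·active(T) = k(T − T_ext)`. The heat
step function is non-increasing and the loss line strictly increasing, so
the crossing is unique: inside a constant step it is a true fixed point;
at a step discontinuity the temperature pins to the threshold and the
element duty-cycles, delivering exactly the loss `k(θ − T_ext)` — the
`mode` field reports which occurred. A thermostat house holds `T = S` at
power `k(S − T_ext)`, capped at the all-elements power `4p`; above the cap
it saturates at `T = T_ext + 4p/k`. With the outdoors at or above the
relevant thresholds/set temperature the house sits passively at `T_ext`
with zero energy (not an error).

Dynamics integrate `C·dT/dt = q(T) − k(T − T_ext)` by explicit Euler
(stability requires `dt < C/k'`, checked before integration; duty-cycling
appears as a small oscillation around the pinned threshold). For the
thermostat regime `q(T)` is a continuously modulated power
`clip(K_p(S − T), 0, 4p)` with `K_p = 50 kW/°C` — a high-gain proportional
controller, so trajectories settle within ~0.1 °C of `S` without bang-bang
chatter. Defaults `p = 1 kW`, `C = 2 kWh/°C`, `dt = 0.01 h` are
illustrative and recorded in the config.

Two towns: house heat-loss coefficients are log-normal (mean 0.15 kW/°C,
CV 0.3); thermostat set temperatures are normal (mean 21 °C, CV 0.05) and
drawn independently of `k`; outdoors is 10 °C. The `k` scale is a sizing
choice: typical thermostat demand `k(S − T_ext) ≈ 1.65 kW` against the
4 kW cap leaves fewer than 0.2% of houses overwhelmed, which is the
premise of the thermostat town's positive temperature–energy correlation
(an overwhelmed thermostat house behaves like an equilibrium house and
dilutes the contrast). Note the towns module states `k` as a distribution
*mean* while curve-parameter draws use *median* = template; both
conventions are stated where used.

## Problem sizes and numerical checks

The replicate suites run 200 cohorts of n = 1000 per system and model for
the sign theorems, 1,000 random loops against a 5,001-point grid-scan
oracle for the solver, 100 random houses against a 100,001-point net-flux
scan plus trajectory tail-averages (0.5 °C band) for the heating engine,
and 100 two-town replicates at 500 houses per town. The oracles recompute
everything from raw formulas in plain numpy so solver and oracle can
disagree. The default report (`eqpoint report`) uses 20 replicates of
n = 500 cohorts per system/model and one 500-house town pair; all seeds
derive from the single run seed, and JSON output is canonically sorted so
a config reproduces its report byte-for-byte.

## Limitations

- Steady-state analysis only: no hormone kinetics, no multi-tier axes
  (e.g. TRH–TSH–FT4), no pulsatile systems. Spiking systems
  (cortisol/ACTH, LH/testosterone) would need a different treatment and
  are deliberately not modeled.
- The published correlations are consumed as printed; raw cohort data are
  not available, so coefficients are inputs, never recomputed outputs.
- Simulated correlation magnitudes are regression anchors for this
  package's defaults, not estimates of any real cohort's coefficient.
- The heating model ignores solar gain, multi-zone coupling and controller
  tuning; the cruise-control analogy is isomorphic and not separately
  implemented.
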