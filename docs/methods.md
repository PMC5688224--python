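# Methods

This note records the model equations as implemented, the parameter choices
that matter, the numerical decisions, and the points where the design was
genuinely open — including the places where this implementation's behaviour
deviates from the published account and why.

## Model

### Plant

The body is a three-link inverted pendulum in the sagittal plane: shank,
thigh and HAT (head-arms-trunk) with revolute joints at the ankle (1), knee
(2) and hip (3), standing on a fixed base. Joint angles θ are relative
rotations; θ = 0 is the fully vertical stack. The sign convention is fixed so
that the reference posture θ⁽⁰⁾ = (−0.1, 0.2, −0.2) rad (forward shank lean,
flexed knee, flexed hip) places the whole-body CoM ≈ 2.9 cm *anterior* of the
ankle — the single physical check that pins all signs. Anterior task
coordinates are positive.

Segment lengths, masses, CoM locations and radii of gyration come from
Winter's proportionality tables as functions of body height h and mass m
(defaults 1.80 m, 80 kg). Both legs are lumped; the feet belong to the base,
so the modeled segments carry 97.1% of body mass. The HAT CoM/gyration
fractions are referenced to Winter's trochanter–glenohumeral length (0.288 h)
while the link itself runs hip-to-vertex (0.470 h); the head point sits at
the vertex end.

Dynamics M(θ)θ̈ + C(θ,θ̇)θ̇ + N(θ) = T are evaluated in closed form: the
planar-chain inertia matrix is assembled in absolute segment angles, where it
has the classic h_jk·cos(φ_j − φ_k) structure, and transformed to relative
coordinates with the constant lower-triangular map φ = Lθ. The Coriolis
matrix uses Christoffel symbols, so Ṁ − 2C is exactly skew-symmetric; the
simulation kernel uses the equivalent velocity-product force vector directly.
Everything is validated in the tests against a numeric Euler–Lagrange oracle
(central differences of the energies, agreement ≤ 1e-6 relative) and
finite-difference Jacobians.

### Muscles and reflexes

Each joint carries one lumped agonist–antagonist pair under threshold
(λ-model) control:

    E_AG = exp[α_E(θ̂ − λ + ρ + μ(θ̂̇ − λ̇))]⁺ − 1
    E_AN = exp[−α_E(θ̂ − λ − ρ + μ(θ̂̇ − λ̇))]⁺ − 1

with α_E = 12 rad⁻¹, velocity weight μ = 0.1 s and co-contraction
ρ = 0.01 rad. Activations above 75% of the ceiling E_max = 10 continue on a
hyperbolic branch Ẽ = c₁/(E + c₂) + c₃ whose constants are solved from value
and slope continuity at the crossover and the asymptote E_max
(c₁ = −6.25, c₂ = −5, c₃ = 10 at the defaults). Net activation maps to
steady-state torque through

    A = [[10.94, 1.10, 0], [0, 7.43, 1.20], [0, 0.94, 9.10]] N·m,

low-pass filtered by critically damped second-order calcium kinetics
(τ_m = 15 ms, unit DC gain). Viscous damping is −Bθ̇ with B ∝ A
(κ ≈ 2.29 s), and passive elastic torques are sums of two exponentials per
joint (plus a knee hard stop against hyperextension) with the
Riener–Edrich coefficient structure shipped as a YAML asset
(`quietstance/data/passive_elastic.yaml`). Angle/torque conventions of that
source are mapped so that every passive curve is restoring around upright —
the mapping is pinned by slope checks in the tests, not assumed.

**Motor noise.** Signal-dependent motor noise multiplies each motoneuron
pool's output: E = −E_AG·η_AG + E_AN·η_AN with independent η ~ N(1, σ_m),
σ_m = 0.01, clipped at zero. Attaching the noise per pool (rather than to the
net sum) keeps physiological force fluctuations alive under symmetric
co-contraction — essential for the all-feedback-cut experiment below — and
reduces to the net-multiplicative law whenever one pool is silent. The
net-multiplicative form is retained in the API (`muscle.net_activation`).

### Passive-field referencing and the reflex operating point

The constant offsets of a transcribed passive-moment model are its least
transferable part (they depend on measurement posture and population), while
the exponential slopes carry the joint-coupling physiology. By default the
offsets are re-referenced so the passive field balances gravity exactly at
the reference posture (`RunConfig.passive_reference`, share configurable via
`passive_load_share`). Two consequences:

1. The initial thresholds are λ⁽⁰⁾ = θ⁽⁰⁾ (zero net activation is required,
   so the closed-form threshold inversion lands on its asinh(0) branch), and
   every reflex pair sits at its co-contracted operating point with
   sensitivity R = ∂E/∂λ = 2α_E e^{α_E ρ} ≈ 27 per joint.
2. That operating point matters for stability: a discrete linear
   eigenanalysis of the loop (including the exact delay lines) shows a
   knee-dominant counter-rotation mode near 6 Hz whose damping changes sign
   when the per-joint gains R_j = α_E(|E_j|+1) exceed ≈ 36, i.e. whenever
   the muscles carry static loads with |E| ≳ 2. With the raw transcribed
   offsets the knee and hip operate at |E| ≈ 2.3–2.8 and the 30-ms reflex
   delay turns the mode into a growing flutter; at the balanced operating
   point the mode is comfortably damped (≈ −4.5 s⁻¹) and the model stands
   for arbitrary trial counts. The raw offsets remain available
   (`passive_reference=False`) for studying that regime.

### Sensing

All noise channels are Ornstein–Uhlenbeck processes
η̇ = −α_η η + ξ with α_η = 5 s⁻¹, integrated by Euler–Maruyama with the
published magnitudes σ scaling the white-noise drive (stationary SD
σ/√(2α_η)). Under the alternative reading (σ as the stationary SD) the joint
variance comes out two orders of magnitude above the published ~1e-5 rad² per
DoF and the model falls; the drive-scaling convention reproduces both stable
35-s standing and the published variance magnitudes, so it is the one
implemented. Delays are exact integer multiples of the 2-ms step
(proprioception 30 ms, body-in-space 120 ms); all signals are held at their
initial values for t < 0 and sensor estimates are primed with true values.

### Control

Task feedback: f_p = −α_ṗ ṗ̂ − α_p̈ p̈̂ with α_ṗ = 12, α_p̈ = 2ζ√α_ṗ
(ζ = 0.5), and f_o = −α_o(ô − o_ref) with α_o = 40. The orientation
reference o_ref defaults to the trunk orientation of the reference posture so
that the closed loop's fixed point is the reference posture itself (the
printed absolute form, recovered with o_ref = 0, drives a ~0.1-rad transient
away from the Van Soest posture because that posture has the trunk off
vertical). There is deliberately no position feedback on p: the head position
diffuses slowly, as it does in real quiet stance.

Schemes C and D transform joint-level feedback F into threshold rates with
the inverse-model calibration λ̇ = R⁻¹A⁻¹M F (+ OU processing noise
σ_λ̇ = 0.001 rad/s). F combines the f_p term — through the ankle-restricted
Jacobian pseudo-inverse (C) or the minimum-norm pseudo-inverse of the full
head Jacobian (D) — with trunk-orientation feedback distributed through the
augmented Jacobian [J_o; J_c] so it cannot move the CoM. R is evaluated
analytically (including the saturation branch) from the sensed state and the
previous step's command, and clamped at 1e-6 of its resting value before
inversion.

Schemes A and B map f_p to the ankle *through the same calibration*
(ankle-restricted). The literal identification λ̇₁ = f_p is not
unit-consistent (f_p lives in head-position units, λ̇ in rad/s), and its
implied gain exceeds the calibrated level by more than an order of magnitude
through the instantaneous μ·λ̇ pathway — far beyond this plant's oscillatory
stability limit at any co-contraction level. Scheme A holds the proximal
thresholds constant and raises knee/hip co-contraction to ρ₂,₃ = 0.15 rad;
scheme B instead runs local PD feedback on every joint around the reference
posture with gains α_θ = 3 s⁻¹, α_θ̇ = 1 (these two are not part of the
published set; they were fixed by a coarse stability search and are marked
as such). Schemes A and B run without the sensory delays by default — with
delays they cannot stand at all — mirroring the comparison protocol.

## Simulation protocol

Stochastic Euler at dt = 2 ms exactly; trials of 35 s with the first 5 s
discarded; N = 48 trials per condition; every trial draws its noise from an
independent substream spawned from the master seed, so (seed, config)
determines every output array bitwise. A trial aborts when any |θ_j| exceeds
1.5 rad or the state leaves the finite range. The compiled kernel is verified
step-for-step (to ~1e-15) against a readable pure-Python composition of the
module functions (`ReferenceLoop`).

Feedback ablations: `outer_cut` sets λ̇ ≡ 0 (reflex loop intact); `all_cut`
freezes both pool activations at their initial values, leaving only motor
noise and passive mechanics. Fall geometry is classified per frame from the
signs of θ − θ⁽⁰⁾: *folding* when at least two joints have moved in opposite
directions, *toppling* otherwise; a configurable deadband (default 0.01 rad)
adds noise robustness, while the replication of the published fall table uses
deadband 0 — the published rule thresholds raw sign changes, and the early
(1-s) percentages are exactly the sign-pattern statistics of small
correlated deviations.

## UCM analysis

Episodes of 30 s are cut from each series starting 10 s in, at most eight per
series (the empirical protocol). For each episode and task variable (CoM,
head position, trunk orientation) the 1×3 Jacobian is linearized at the
episode-mean posture, the sample covariance is projected onto the Jacobian's
null space (k∥ = 2) and its complement (k⊥ = 1), and V∥, V⊥ are the
normalized traces; k∥V∥ + k⊥V⊥ = tr Σ̂ holds to rounding. Decorrelation
surrogates permute each joint's samples independently (marginals preserved
exactly). Variance-vector descriptors: magnitude = Euclidean norm, shape =
stereographic projection of the normalized vector about the equal-variance
pole (1,1,1)/√3 (so equal variances map to the origin), with Box–Cox
normalization by maximum likelihood available for either.

## What the generator reproduces — and what it does not

With the published parameter set the distributed scheme (D) stands 48/48
trials at quiet-stance magnitudes (CoM sd ≈ 3 mm, joint variance
~2–4·10⁻⁵ rad² per DoF), V∥ > V⊥ for all three task variables, both variance
components grow from eyes-open to eyes-closed, decorrelation collapses the
CoM/head UCM effects toward their marginal-variance level and reduces the
trunk-orientation effect to exactly the value implied by the marginals.
Severing the outer loop topples the body (≈ 16/76/98/99% toppling at
1/2/3/4 s over 200 trials); severing everything folds it (toppling ≈ 0%).

Known limitations:

- **Scheme A.** The co-contraction scheme cannot reproduce the published
  direction of its CoM variance ratio here. At the printed ρ₂,₃ = 0.15 the
  stiffened proximal reflex loops sit beyond the oscillatory limit set by
  the calcium-filter lag (instability ≈ +4 s⁻¹ even with zero delay); the
  resulting saturation-bounded limit cycle lives in the low-inertia,
  CoM-invariant joint mode, so V∥ ≫ V⊥. At low co-contraction the loops are
  calm, but gravitational/inertial coupling then deflects the compliant knee
  coherently with ankle sway — again V∥ > V⊥. Intermediate levels fall. The
  corresponding acceptance assertion is left failing rather than weakened.
- The simulator is a plant of its own: its stability boundaries sit close to
  several of the published gains, and three assembly choices (passive-offset
  referencing, per-pool motor noise, calibrated ankle mapping for A/B) were
  resolved *toward the published operating regime*; each is configurable and
  documented above.
- Synthetic sway lacks the slow postural drifts, intermittency and
  inter-subject diversity of human data; passing tests show the model's
  internal consistency and the qualitative variance structure, not fidelity
  to any individual's sway.
- No frontal plane, no foot/ground compliance, no perturbation-response
  experiments, no fitting to individual subjects.

## Numerical choices

- Explicit (stochastic) Euler throughout at dt = 2 ms — delays stay exact;
  no adaptive stepping. First-order convergence is verified by step-halving.
- Reflex exponents are clamped at 30 before `expm1`: beyond the saturation
  crossover the hyperbolic branch is flat, so the clamp only guards float
  overflow (unclamped, the saturation-slope product could evaluate 0·inf).
- 3×3 linear solves in the kernel use closed-form cofactors; pseudo-inverses
  in the API use SVD with relative cutoff 1e-12.
- Per-trial, per-channel RNG substreams via `numpy` `SeedSequence.spawn`.
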