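# Methods

This note documents the physical model implemented by `nemadischarge`, its
assumptions, numerical choices and limitations. It is written for a reader
who wants to judge what the computations do and do not show.

## The model in one paragraph

A nematocyst is treated as a spherical capsule of radius R whose polyanionic
matrix acquires a net negative charge when proteolysis releases H+ that
out-diffuses through the semipermeable wall. The trapped charge stores a
Coulomb self-energy U and exerts an outward Coulomb pressure p = −∂U/∂V on
the capsule. The stylet — an axisymmetric "carrot" held at the exit orifice
by an elastic mini-collagen collar — is pushed out by that pressure; the
static balance of thrust against the collar's restoring force loses its
solution at a saddle-node (fold), and the fold pressure is the ejection
threshold. Discharge is orchestrated as five quasi-static stages (trigger,
charge buildup, Coulomb explosion, distension, eversion), of which only
stages 2–3 carry quantitative physics.

## Electrostatics

### Charge profile

The steady screening equation for the scaled charge density
y = ρ/(e n₀) ∈ (−1, 0] in spherical symmetry is

    (1/x²) d/dx [ x² d/dx ln(1 + y) ] = y,     x = λ r,

with inverse screening length λ = sqrt(μ e n₀ / (ε D)) (the unique
dimensionally consistent combination of the H+ mobility μ, diffusion
constant D, initial density n₀ and permittivity ε). Near the wall, and for
|y| ≪ 1, the profile reduces to the exponential boundary layer
ρ(r) = ρ₀ e^{−λ(R−r)} with ρ₀ = −e n₀ (complete depletion at the wall).
This *linearized* profile is the workhorse of the package because it admits
closed forms in the single parameter X = λR.

Note on the small-amplitude limit: the linearization of the *spherical*
equation regular at the centre is y ∝ sinh(x)/x, which near the surface
equals the planar exponential only up to the curvature factor X/x. The
exponential model is therefore a large-capsule (X ≫ 1) approximation; tests
check the solver against sinh(x)/x exactly and against the exponential only
at X = 50.

### Closed forms and limits

With f(X) = X³ − 7/2 X² + 11/2 X − 11/4 − 4(X−1)e^{−X} − 5/4 e^{−2X},
g(X) = X² − 2X + 2 − 2e^{−X} (the scaled enclosed-charge integral) and
h(X) = X − 1 + e^{−X}:

    U   = 2π ρ₀² f(X) / (λ⁵ ε)
    φ   = ρ₀ h(X) / (λ² ε)
    Q   = 4π ρ₀ g(X) / λ³
    p   = ρ₀² / (2 ε λ² X²) · [ −f′(X) + 2 g′(X) f(X) / g(X) ]

The pressure is the derivative −∂U/∂V taken at *fixed total charge Q* (and
fixed λ); this convention reproduces the classical homogeneous-sphere limit
p → ρ₀²R²/(15ε) as X → 0 and the charged-capacitor limit p → σ²/(2ε)
(σ = ρ₀/λ) as X → ∞. The Donnan potential φ is referenced to the
discharged exterior: φ = (1/ε)∫₀ᴿ ρ(r) r dr is the potential at the capsule
centre, with limits ρ₀R²/(2ε) (uniform sphere) and σR/ε (shell) — the
classical centre potentials of those distributions.

The asymptotic approach to the limits is slow and first-order:

    p / (ρ₀²R²/15ε) = 1 − X/2 + O(X²)        (X → 0)
    p / (σ²/2ε)     = 1 − 3/X + O(1/X²)      (X → ∞)
    φ / (σR/ε)      = 1 − 1/X + ...          (X → ∞)

so e.g. the shell-limit pressure is still 0.3% low at X = 10³. Tests assert
these measured rates rather than idealized instant convergence.

### Numerics

* **Cancellation at small X.** f, g, h and the pressure bracket vanish to
  orders X⁵, X³, X², X⁴; direct float64 evaluation loses all significance
  below X ≈ 0.1. For X < 0.5 they are evaluated from their exact Taylor
  coefficients (simple closed rational forms, 42 terms, convergent far
  beyond the cutoff); above 0.5 the direct expressions are used. The two
  branches agree to ~1e−12 at the crossover.
* **Nonlinear BVP.** Substituting w = ln(1+y) gives Lap w = e^w − 1, solved
  with second-order finite differences on a uniform grid (default 512
  intervals), regularity dw/dx(0) = 0 via a symmetric ghost node (the
  spherical Laplacian tends to 3w″(0) at the origin), and a damped Newton
  iteration (tridiagonal Jacobian, banded solve; step halving while the
  residual does not decrease; update-norm tolerance 1e−10, ≤ 200
  iterations). The wall value y(X) is a free boundary parameter defaulting
  to −0.99: near-complete depletion without touching the logarithmic
  singularity at y = −1.
* **Oracles.** The self-energy is cross-checked by shell quadrature
  U = (1/ε)∫ q(r) ρ(r) r dr (midpoint rule), the potential by
  φ(0) = (1/ε)∫ ρ r dr, and the pressure by central finite differences of
  U(R) at fixed Q (second-order in dR). A verbatim transcription of the
  long-form pressure expression is also kept; it differs from the −dU/dV
  derivative by one exponential in its enclosed-charge denominator, and the
  public pressure routine warns when the two deviate by more than 1e−3
  relative while always returning the derivative-validated value.

## Mechanics

Scaled units: lengths in stylet lengths l, pressures in units of the collar
modulus Y.

* The carrot profile β(ξ) = aξ(l−ξ)/(d+ξ) has its apex where
  ξ² + 2dξ − ld = 0, i.e. ξ₁ = sqrt(d(l+d)) − d, with
  β_x = a(l + 2d − 2 sqrt(d(l+d))). (The root must include the −d term;
  without it the slope does not vanish, while the β_x closed form is
  unchanged.)
* The collar rests on the descending flank: the contact point ξ₊(β) ≥ ξ₁ is
  the larger root of the shape quadratic. The balancing pressure

      p(β) = 2αY (β − β₀) (−β′(ξ₊(β))) / (β₀ β²)

  vanishes at β = β₀ and at the apex and is maximized in between; the
  maximum is the fold threshold. Numerically: a 4096-point geometric sweep
  of β ∈ (β₀, β_x] (the fold can sit arbitrarily close to β₀ when the
  collar is narrow) followed by bounded golden-section refinement
  (xatol 1e−13·β_x). Equilibria below threshold are found by bracketed
  root-finding on the rising branch, which certifies existence just below
  the fold and non-existence above it.
* When the collar is narrow (β₀ = r₀ ≪ β_x) the contact point stays near
  the tip where −β′ ≈ a(1−d)/l², and maximizing (β−β₀)/β² at β = 2β₀ gives
  the closed-form threshold P ≈ (1−d) Y a α / (2 r₀²). For the reference
  configuration (a = 0.2, l = 1, d = 0.01, α = 1, β₀ = r₀ = 0.005, Y = 1)
  this is exactly 3960; the numeric fold gives 3956.1 (−0.1%).
* Displacement: δ(p) = ξ₊(β(p)) − ξ₊(β₀) (negative; the contact point
  slides toward the apex as the stylet advances). δ(0) = 0, |δ| is strictly
  increasing, and dδ/dp diverges at the fold — the signature of the
  saddle-node.
* Peak acceleration: from the thrust balance, f_max = P_thres π R_x²/m with
  R_x defaulting to β_x. A second, parametric estimate
  f_max = Yαπa³(1−d)²(1.18 + 7d)/(m r₀²) is evaluated verbatim; its
  prefactor is not derivable from the thrust balance composed with the
  small-collar threshold (the ratio of the two estimates is ≈ 3.7 at the
  reference configuration), so the package reports both and their ratio
  rather than asserting agreement.

## Discharge orchestration

There is no time-evolution law for the H+ efflux, so the simulator consumes
an explicit monotone depletion schedule χ ∈ [0, 1] (default: 100 uniform
steps). At each step ρ₀(χ) = −e n₀ χ, hence p(χ) = χ² p_full. Stage 3
(operculum opening) fires at p ≥ p_operculum, a free parameter defaulting
to half the fold threshold (the model names the first threshold but never
quantifies it); ejection fires at p ≥ P_thres, after which stages 4–5 are
recorded as bookkeeping (stage 5 carries the eversion time
tubule_length / eversion_speed; neither stage has a governing equation).
Runs are fully deterministic.

The default scaled-unit configuration uses n₀ = 280, μ = 1e−4, D = ε = e =
R = 1, chosen once so that X ≈ 0.17 (nearly homogeneous regime) and the
full-depletion pressure (≈ 4811 Y) clears the stylet threshold (≈ 3956 Y)
with ~20% margin — the model requires the pressure to cross both thresholds
but prescribes neither the transport constants nor the margin. Osmotic
contributions to the driving pressure are not modelled; only the Coulomb
term is quantitative.

## QCM reversibility rule

The classifier formalizes a verbal criterion: collagen survives temperature
cycling iff revisiting a temperature reproduces the frequency shift. Rule:
group samples by temperature (single-linkage within 1 °C), drop the first
visit of each group as baseline settling (the initial low-temperature
reading precedes any cycling), ignore groups with fewer than two remaining
visits, and call the series reversible iff every group's Δν spread
(max − min) is ≤ 100 Hz. The 100 Hz default is the smallest round value
separating the reference series' spreads (0 Hz for the 37 °C-cycled series
vs 450 Hz for the 45 °C-denatured one); both tolerances are configurable.
The rule is deliberately insensitive to isolated temperature excursions
(singletons carry no revisit information). It judges only revisit
consistency — it does not model QCM physics (Sauerbrey mass loading,
viscoelastic corrections) and cannot distinguish *why* a series drifts.

## What the defaults do and do not show

The scaled-unit defaults reproduce the model's internal consistency: the
fold threshold from the full force balance agrees with its closed form, the
electrostatic closed forms agree with brute-force quadrature, and the
five-stage run crosses its thresholds in order. They do not constitute a
fit to any measured nematocyst: absolute SI predictions require transport
constants, capsule size, collar modulus and stylet mass that must be
supplied by experiment, and literature magnitudes (GPa-scale pressures,
m/s ejection speeds, ~10⁶ g accelerations) are reachable only with such
unstated parameters. The package's quantitative claims are therefore the
dimensionless/scaled ones tested in `tests/`.

## Known limitations

* Quasi-static only: no inertial dynamics, no time-resolved trajectory of
  the stylet or tubule; eversion is bookkeeping.
* Spherical capsules and axisymmetric stylets only.
* The linearized profile assumes complete wall depletion; the nonlinear BVP
  relaxes the amplitude assumption but keeps an imposed wall value.
* The two acceleration estimates disagree by a constant factor (see above);
  both are reported.
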