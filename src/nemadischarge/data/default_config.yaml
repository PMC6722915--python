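# Default run configuration (scaled units: lengths in stylet lengths l,
# pressures in units of the collar modulus Y).
#
# Shape/restraint values are the reference carrot-stylet configuration
# (a=0.2, l=1, d=0.01 with a narrow collar beta0=r0=0.005), whose closed-form
# ejection threshold is 3960 Y.  The transport constants are chosen so the
# fully depleted capsule (chi=1) develops a Coulomb pressure about 20% above
# that threshold: X = lam*R ~ 0.17, so the capsule is in the nearly
# homogeneous regime where p ~ rho0^2 R^2 / (15 eps).
schema_version: 1

transport:
  n0: 280.0
  mu: 1.0e-4
  D: 1.0
  eps: 1.0
  e: 1.0

geometry:
  R: 1.0

shape:
  a: 0.2
  l: 1.0
  d: 0.01

restraint:
  Y: 1.0
  alpha: 1.0
  beta0: 0.005
  r0: 0.005

inertia:
  m: 1.0
  # Rx defaults to the apex radius beta_x

discharge:
  n_steps: 100
  chi_max: 1.0
  eversion_speed: 1.0
  tubule_length: 1.0
  # p_operculum defaults to half the numeric fold threshold

electrostatics:
  y_surface: -0.99
  n_grid: 512
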