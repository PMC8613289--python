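# Default model configuration (arbitrary concentration / time / length units).
#
# The kinetic values are a documented constraint-satisfying default set: every
# inequality the model imposes on its rate constants holds, the no-catalysis
# equilibrium has a higher nuclear than cytoplasmic G-actin mean, and the full
# catalytic scenario visibly depletes nuclear G-actin within 400 time units.

parameters:
  # basal actin turnover
  gamma_Gc: 0.1         # G -> F polymerization, 1/time
  gamma_Fc: 0.1         # F -> G depolymerization, 1/time
  # cofilin-actin shuttle (import carrier): fast association in cytoplasm,
  # fast dissociation in nucleus
  alpha_Xi_c: 1.0       # 1/(conc*time)
  gamma_Xi_c: 0.1       # 1/time
  alpha_Xi_n: 0.1
  gamma_Xi_n: 1.0
  # profilin-actin shuttle (export carrier): mirrored ordering
  alpha_Ups_c: 0.1
  gamma_Ups_c: 1.0
  alpha_Ups_n: 1.0
  gamma_Ups_n: 0.1
  # cofilin phosphorylation cycle
  alpha_Theta_c: 0.1    # phosphorylation, 1/time
  gamma_Theta_c: 0.1    # dephosphorylation, 1/time
  # catalytic enhancements (per unit E)
  mu1: 0.5              # polymerization boost
  mu2: 50.0             # cofilin-phosphorylation boost
  gamma_Ec: 0.0         # catalytic factor is conserved
  ec_decay: zeroth_order
  # membrane transfer coefficients, length/time
  beta_Pc: 0.3
  beta_Pn: 0.3
  beta_Cc: 0.3
  beta_Cn: 0.3
  beta_Xi_c: 0.45       # one-way cofilin-actin import
  beta_Ups_n: 0.15      # one-way profilin-actin export
  # diffusion coefficients, length^2/time; nuclear >> cytoplasmic so nuclear
  # profiles stay nearly flat; F-actin and the catalytic factor do not diffuse
  D:
    G_c: 0.01
    F_c: 0.0
    C_c: 0.01
    Xi_c: 0.01
    P_c: 0.01
    Ups_c: 0.01
    Theta_c: 0.01
    E_c: 0.0
    G_n: 0.1
    C_n: 0.1
    Xi_n: 0.1
    P_n: 0.1
    Ups_n: 0.1

geometry:
  p1: [0.0, 0.0]        # nucleus centre
  r1: 0.3               # nucleus radius
  p2: [0.0, 0.0]        # cell centre (concentric default)
  r2: 0.9               # outer cell radius
  p3: [0.36, 0.0]       # catalytic-region centre (tangent to the nucleus)
  r3: 0.06              # catalytic-region radius (0.2 * r1)
  Ec_init: 1.0          # catalytic-factor initial level

grid:
  nx: 201
  ny: 201
  extent: [[-1.0, 1.0], [-1.0, 1.0]]

solver:
  dt: 0.01
  t_end: 400.0
  output_every: 100
  positivity_tolerance: 1.0e-10

scenario:
  name: full_model
  mu1_active: true
  mu2_active: true
  region_distance: 0.0
  t_end: 400.0
  snapshot_times: [0.0, 50.0, 400.0]
  seed: 0

equilibration:
  tolerance: 1.0e-6     # max relative change of any compartment mean, per time unit
  max_steps: 100000
  check_every: 100
  # spatially uniform seed concentrations (per compartment)
  seeds:
    G_c: 1.0
    F_c: 1.0
    C_c: 1.0
    Xi_c: 0.0
    P_c: 1.0
    Ups_c: 0.0
    Theta_c: 0.0
    E_c: 0.0
    G_n: 1.0
    C_n: 1.0
    Xi_n: 0.0
    P_n: 1.0
    Ups_n: 0.0
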