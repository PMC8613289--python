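# Methods

## Model

`nucactin` simulates the nucleocytoplasmic shuttling of monomeric (G-) actin
in a single static cell cross-section. The cell is two nested disks on a
square domain: a nucleus Ω_n = {‖x − p1‖ < r1} and a cytoplasmic annulus
Ω_c = {‖x − p2‖ < r2} \ Ω_n, separated by the nuclear envelope Γ_n and
bounded outside by the plasma membrane Γ_c. The model tracks 13 reacting,
diffusing species:

| compartment | species |
|---|---|
| cytoplasm | G-actin `G_c`, F-actin `F_c`, cofilin `C_c`, cofilin–actin `Xi_c`, profilin `P_c`, profilin–actin `Ups_c`, phospho-cofilin `Theta_c`, catalytic factor `E_c` |
| nucleus | `G_n`, `C_n`, `Xi_n`, `P_n`, `Ups_n` |

Each species obeys ∂u/∂t = D ∇²u + f(u) in its compartment with mass-action
kinetics:

* **Polymerization** (cytoplasm only): G_c → F_c at rate
  γ_Gc (1 + μ1 E_c) G_c; depolymerization F_c → G_c at γ_Fc F_c.
* **Cofilin shuttle**: reversible association C + G ⇌ Ξ in both compartments
  (rates α_Ξ·, γ_Ξ·).
* **Profilin shuttle**: reversible association P + G ⇌ Υ in both compartments
  (rates α_Υ·, γ_Υ·).
* **Cofilin phosphorylation** (cytoplasm only): C_c → Θ_c at rate
  α_Θc (1 + μ2 E_c) C_c; dephosphorylation Θ_c → C_c at γ_Θc Θ_c.
* **Catalytic factor** E_c: non-diffusing and non-decaying (its printed decay
  rate γ_Ec is constrained to zero; the `ec_decay` config switch selects the
  zeroth-order form of the inert decay term). It is initialized as the
  indicator of a small disk B(p3, r3) intersected with the cytoplasm —
  a localized catalytic region that by default sits tangent to the nuclear
  envelope. The discrete field uses fractional cell coverage (supersampling)
  rescaled so the conserved catalytic mass equals its continuum value
  Ec_init · area(B ∩ Ω_c) exactly on every grid; with naive cell-centre
  assignment the region's mass is grid-quantized and the experiment readouts
  jump between resolutions.

Free G-actin does not cross the nuclear envelope. Transport is entirely
carrier-mediated, via Robin-type transfer fluxes on Γ_n (positive into the
nucleus):

| species | flux on Γ_n |
|---|---|
| cofilin C | β_Cc·C_c − β_Cn·C_n (bidirectional) |
| profilin P | β_Pc·P_c − β_Pn·P_n (bidirectional) |
| cofilin–actin Ξ | β_Ξc·Ξ_c (import only) |
| profilin–actin Υ | −β_Υn·Υ_n (export only) |
| G, F, Θ, E | no flux |

All species satisfy no-flux (Neumann) conditions on Γ_c, so total actin
(G + F + Ξ + Υ over both compartments), total cofilin (C + Ξ + Θ), total
profilin (P + Υ) and total catalytic factor are conserved exactly.

## Parameter constraints and defaults

The defaults (packaged in `data/default_config.yaml`) satisfy the structural
constraints that make the shuttle directional, checked by
`validate_parameters` (12 named checks):

* D[F_c] = D[E_c] = 0 and γ_Ec = 0 (immobile filaments, conserved catalyst);
* α_Ξc > α_Ξn and γ_Ξc < γ_Ξn: cofilin–actin forms in the cytoplasm and
  releases in the nucleus (import carrier);
* α_Υn > α_Υc and γ_Υn < γ_Υc: profilin–actin forms in the nucleus and
  releases in the cytoplasm (export carrier);
* β_Cc = β_Cn and β_Pc = β_Pn: free carriers cross symmetrically;
* β_Ξc > β_Υn: import outruns export, producing the nuclear G-actin excess;
* nuclear diffusivities exceed cytoplasmic ones for shuttling species.

Default magnitudes: association rates of the "favoured" direction 1.0,
of the disfavoured direction 0.1 (and vice versa for dissociations);
γ_Gc = γ_Fc = 0.1; α_Θc = γ_Θc = 0.1; μ1 = 0.5, μ2 = 50 (phosphorylation is
the strongly catalysed pathway); β_C = β_P = 0.3, β_Ξc = 0.45, β_Υn = 0.15;
cytoplasmic D = 0.01, nuclear D = 0.1. These were calibrated once, at design
time, to meet three qualitative requirements: all constraints hold with
margin, the equilibrium shows a clear nuclear G-actin excess
(G_n/G_c ≈ 2.4), and the full model produces visible nuclear depletion
within 400 time units. β_Ξc = 0.45 (not larger) also keeps the explicit
transfer update stable on the default grid (see below). `sample_constrained_parameters`
draws random sets from disjoint per-parameter ranges bracketing these
defaults, so every draw satisfies the constraints.

Geometry defaults: r1 = 0.3, r2 = 0.9, concentric at the origin; catalytic
region r3 = 0.06 tangent to the nucleus at p3 = (0.36, 0); domain
[−1, 1]²; E_c initial value 1 inside the region.

## Numerics

Finite-volume discretization on a uniform Cartesian grid of square cells
(default 201×201, h ≈ 0.01); a cell belongs to the compartment containing
its centre. Per time step dt = 0.01 the solver applies Lie splitting:

1. **Reactions**: explicit Euler on every cell (pointwise mass-action terms
   evaluated at the beginning-of-step state).
2. **Membrane transfers**: explicit flux exchange across cytoplasm–nucleus
   cell faces, amount = flux × face length × dt, withdrawn from the donor
   cell and deposited in the acceptor so the pairwise exchange conserves
   mass to round-off. A donor-cell limiter scales the withdrawal if it would
   exceed the donor's content (never triggered at the defaults; counted and
   reported when it is). Stability requires β dt / h < 1/2; the largest
   coefficient β_Ξc = 0.45 gives 0.452 at 201².
3. **Diffusion**: backward Euler, one sparse LU factorization per
   (compartment, diffusivity) pair, cached and reused across all steps and
   species sharing it, with multi-right-hand-side solves. The restricted
   5-point Laplacian with reflective (Neumann) closure is an M-matrix, so
   the implicit solve is unconditionally stable, positivity-preserving and
   exactly mass-conserving.

The hot loop operates on compartment-packed 1-D vectors (exterior cells are
never touched). Concentrations are clipped at zero only within a 1e-10
tolerance; a larger negative value raises an error. Two independent oracles
validate the scheme: a fully explicit reference integrator at dt/100 (all
compartment averages agree within 0.5% over 50 coarse steps) and the
closed-form decay rate D(π/L)² of a cosine eigenmode on a rectangle (within
1% at 201 grid points).

## In-silico experiments

1. **Equilibration**: the catalysis-free system (E_c = 0) is relaxed from
   uniform seeds (free pools 1.0, complexes and phospho-cofilin 0) until the
   largest relative change of any compartment mean drops below 1e-6 per time
   unit; the spatially constant compartment averages are then used as the
   initial condition of every experiment, so all scenario variants start
   identically.
2. **Full model**: install the localized E_c field at t = 0 with both
   catalysed pathways active and integrate 400 time units (snapshots at
   t = 0, 50, 400). Readout: the nuclear G-actin depletion fraction
   Δ = 1 − mean G_n(t_end) / mean G_n(0).
3. **Knockout matrix**: the four on/off combinations of the catalysed
   polymerization (μ1) and catalysed phosphorylation (μ2) pathways, all from
   the shared equilibrium. The headline prediction is the ordering
   Δ(μ1 = 0) > Δ(μ2 = 0): depletion is driven by catalysed phosphorylation,
   while knocking out catalysed polymerization barely matters.
4. **Robustness**: the two single-pathway knockouts re-run over ≥ 20 sampled
   constraint-satisfying parameter sets; the report records the fraction of
   sets in which the ordering holds.
5. **Relocation**: the catalytic region is moved from tangent (d = 0) along
   the ray through p3 to the largest admissible distance from the nuclear
   surface; Δ decreases with distance.

## Problem sizes

Sizes are this package's own choices, balancing fidelity against a
single-CPU budget (the model is deterministic, so smaller grids change
values smoothly, not qualitatively):

* conservation / direction-pattern runs: 101×101, 400 time units;
* knockout matrix and relocation: 41×41, 400 time units;
* convergence studies (100-time-unit horizon): dt-halving at 41×41;
  grid doubling at 82×82 → 164×164, the coarsest pair on which the catalytic
  region (radius 0.06 ≈ 2.5 cells at 82×82) is resolved — at 41×41 its radius
  is ~1.2 cells and the depletion readout still sits ~9% from its converged
  value even with the mass-normalized initial field;
* robustness sweep: 20 parameter sets at 41×41, 50 time units, equilibration
  tolerance 1e-5;
* oracle comparison: 81×81, 50 coarse steps after a 5-time-unit pre-relaxation
  that removes the artificial discontinuity of the uniform seed state;
* analytic eigenmode: 201×10 rectangle.

## Limitations

* The geometry is static and two-dimensional; no membrane deformation,
  cell motility or 3-D effects.
* Carrier-mediated transport is reduced to linear Robin fluxes; saturable
  transporter kinetics (importin/exportin machinery) are not modelled.
* The catalytic factor is a fixed indicator field, not a trafficked species;
  endosome dynamics are outside scope.
* Explicit reaction/transfer splitting is first order in time; dt must
  resolve the fastest reaction (rates ≤ O(1) at the defaults, dt = 0.01).
* Equilibration returns flattened compartment averages, not the true spatial
  equilibrium profile; scenario runs therefore begin with a small, decaying
  re-profiling transient (compartment means return to within 0.01% of the
  averages within 100 time units at 41×41).
* Units are nondimensional model units throughout; mapping to physical
  concentrations and times requires external calibration.
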