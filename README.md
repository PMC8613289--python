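# nucactin

A two-compartment reaction–diffusion simulator of nucleocytoplasmic G-actin
shuttling.

## The scientific problem

The concentration of monomeric (G-) actin in the cell nucleus gates
MRTF/SRF-dependent transcription: when nuclear G-actin falls, MRTF
accumulates in the nucleus and switches the programme on. G-actin itself
cannot cross the nuclear envelope — it is carried in by cofilin and carried
out by profilin. A catalytic factor localized just outside the nucleus
(nuclear-captured signalling endosomes) can tip this balance by boosting two
cytoplasmic reactions: actin polymerization (drawing monomer into filaments)
and cofilin phosphorylation (inactivating the import carrier). `nucactin`
asks the quantitative question: which of the two catalysed pathways actually
depletes the nuclear G-actin pool, and does the answer depend on where the
catalytic region sits?

## The model

Two nested disks on a square domain — a nucleus inside a cytoplasmic annulus
— carry 13 species (8 cytoplasmic, 5 nuclear) with mass-action kinetics:
polymerization G ⇌ F, carrier association C + G ⇌ Ξ (cofilin–actin) and
P + G ⇌ Υ (profilin–actin) in both compartments, cofilin phosphorylation
C ⇌ Θ in the cytoplasm, and a static localized catalytic field E_c that
multiplies the polymerization rate by (1 + μ1 E_c) and the phosphorylation
rate by (1 + μ2 E_c). Membrane transfer across the nuclear envelope is
carrier-mediated: free cofilin and profilin cross bidirectionally,
cofilin–actin is imported only, profilin–actin is exported only, and free
G-actin, F-actin, phospho-cofilin and the catalytic factor never cross.
Constraint-validated default parameters make the shuttle directional, so
the equilibrium nuclear G-actin concentration exceeds the cytoplasmic one.

The solver is a conservative finite-volume scheme with operator splitting:
explicit reactions and membrane transfers, backward-Euler diffusion with
cached sparse factorizations. Total actin, cofilin, profilin and catalytic
factor are conserved to round-off. See `docs/methods.md` for the full
model, discretization and design rationale.

## Worked example

The headline in-silico experiment — equilibrate the catalysis-free cell,
switch on the catalytic region, and knock out each catalysed pathway in
turn:

```python
import nucactin as na

config = na.load_config()                      # packaged defaults
spec = config.build_scenario().replace(
    nx=41, ny=41, t_end=400.0, snapshot_times=(),
)
report, results = na.knockout_comparison(spec)
print(report.to_string(index=False))
```

Output (41×41 grid, about three minutes on one CPU):

```text
scenario  mu1_active  mu2_active  mean_Gn_0  mean_Gn_end  depletion
    both        True        True   1.383842     1.173824   0.151764
mu2_only       False        True   1.383842     1.175443   0.150594
mu1_only        True       False   1.383842     1.382066   0.001283
 neither       False       False   1.383842     1.383864  -0.000016
```

Reading the table: `mu2_only` keeps only catalysed phosphorylation (the
catalysed-polymerization pathway is knocked out, μ1 = 0) and still produces
almost the entire nuclear G-actin depletion of the full model, while
`mu1_only` (μ2 = 0) barely moves it — catalysed cofilin phosphorylation,
not polymerization, empties the nuclear pool. The `neither` control stays at
equilibrium.

Moving the catalytic region away from the nuclear surface weakens the
effect:

```python
dmax = na.max_region_distance(config.geometry)      # 0.48 model units
table, _ = na.relocation_comparison(spec, [0.0, dmax])
print(table.to_string(index=False))
```

```text
 distance  depletion
     0.00   0.151764
     0.48   0.017058
```

Placing the catalytic region at the far side of the cytoplasm cuts the
mobilized nuclear G-actin by roughly a factor of nine.

The same experiments are available from the command line:

```bash
nucactin equilibrate --out out/eq --grid 41
nucactin run        --out out/run --grid 41     # summary.csv, NetCDF + PNG snapshots
nucactin knockouts  --out out/ko  --grid 41
nucactin relocate   --out out/rel --grid 41 --distances 0,0.48
```

Every output directory receives a `manifest.json` with the full
configuration, seed, conservation drift and solver event counters; time
series are CSV, snapshots NetCDF (plus optional PNG renderings of the
combined G-actin field).

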