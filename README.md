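# notchisland

Mechanically modulated Notch–Delta–Jagged lateral inhibition on circular
multicellular islands.

## The problem

Bipotential liver progenitor cells cultured on circular micropatterned
islands (~600 µm) differentiate in a radial pattern: cells at the island rim
become biliary (OPN+), interior cells become hepatocytic (HNF4α+), with the
fate bifurcation at normalized radius 0.95. The rim also exerts high
substrate traction while the interior carries high cell–cell tension, and
active Notch signaling (Hes1) is enriched ~2-fold at the rim. `notchisland`
implements a computational model of this system for researchers studying how
intercellular signaling and tissue mechanics cooperate to pattern progenitor
fate: a per-cell ODE model of Notch signaling on a polygonal disk lattice,
with the mechanical fields coupled into receptor–ligand trans-activation,
plus the quantification conventions used to compare simulations with imaged
islands and a synthetic per-cell data generator with the observed radial
statistics.

## The model

Each cell *i* on the lattice carries Notch receptor *N*<sub>R</sub>, cleaved
intracellular domain NICD, ligands Dll1 (*D*) and Jag1 (*J*), and a lumped
Notch-target readout NT:

```
dN_R,i = betaN·NT_i^h/(1+NT_i^h) − k_tD·N_R,i·D_nb·A_i − k_cD·N_R,i·D_i
         − k_tJ·N_R,i·J_nb·A_i − N_R,i
dNICD_i = betaNICD·( T_D/(1+T_D) + T_J/(1+T_J) ) − NICD_i
dD_i   = betaD/(1+NT_i^h) − k_tD·N_R,nb·D_i·A_i − k_cD·N_R,i·D_i − D_i
dJ_i   = betaJ − k_tJ·N_R,nb·J_i·A_i − J_i
dNT_i  = NICD_i − NT_i
```

where `X_nb` is the cumulative sum of species X over the adjacency
neighbors, `T_D = k_tD·N_R,i·D_nb·A_i`, `T_J = k_tJ·N_R,i·J_nb·A_i`, and the
mechanics enter through the per-cell trans-activation multiplier

```
A_i = S_i / (0.1 + C_neighbor,i),   S_i = ECAD_i·Traction_i,
C_neighbor,i = Σ_{j∈N(i)} ECAD_j·CellCellForce_j
```

Dll1 is parameterized as predominantly cis-inhibitory (k_cD = 22,
k_tD = 0.3) and Jag1 as purely trans-activating (k_tJ = 10). Traction rises
exponentially at the rim (where it is max-normalized to 1), cell–cell force
is its inverse, and E-Cadherin is flat in the interior with a rim rise — so
A is ~50× larger at the rim than in the interior, converting the classic
salt-and-pepper lateral-inhibition pattern into a boundary-restricted ring
of Notch activity. In-silico perturbations scale single parameters: ligand
knockdowns reduce betaD/betaJ by 75%, E-Cadherin knockdown scales the ECAD
field by 70%, EGF adds `egf·N_R` inside the receptor-expression Hill
function, and TGFβ2 upregulates both ligands and adds a force-gated
Dll1-dependent induction of NT.

## Worked example

```python
from notchisland import (ModelParams, analytic_fields, force_free_fields,
                         generate_lattice, neighbor_anticorrelation,
                         region_stats, simulate)

lat = generate_lattice(400, seed=1)          # 400-cell disk island
p = ModelParams()

nt_ff = simulate(lat, force_free_fields(lat), p, t_end=1000, seed=1).final_nt()
print(neighbor_anticorrelation(nt_ff, lat))  # -0.117  (salt and pepper)

nt = simulate(lat, analytic_fields(lat), p, t_end=1000, seed=1).final_nt()
rs = region_stats(nt, lat.radius)            # boundary = radius >= 0.95
print(rs.boundary_mean, rs.interior_mean)    # 1.400    1.6e-29
```

Without mechanics, adjacent cells alternate between high and low Notch
targets (negative Moran's I on the adjacency graph). With the mechanical
fields, Notch-target expression is confined to the rim band: the
boundary mean is ~1.4 in arbitrary units while the interior is
numerically zero, mirroring the boundary-restricted OPN pattern.

The numbered scripts under `analysis/` run the full study: lattice
construction, mechanical fields, the base-model regimes, the 12-condition
scenario battery (genotype × treatment), synthetic island tables, and the
model-vs-data comparison. Each writes its tables under `results/`. The
same pipeline is scriptable from the shell:

```
notchisland synthgen --seed 1 --out cells.csv
notchisland battery --config config.yaml
```

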