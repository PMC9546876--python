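# Methods

## Lattice construction

A simulated island is a tessellation of the unit disk into `n_cells`
polygonal cells (default 400, the experimental islands' approximate cell
count). Generator points are drawn area-uniformly in the disk and relaxed
by Lloyd iteration — each point moves to the centroid of its disk-clipped
Voronoi cell — toward a centroidal Voronoi tessellation with near-equal
areas. Voronoi regions are bounded by mirroring each generator radially
across the circle before tessellation, and clipped against a 256-gon
approximation of the disk (area error ~1e-4 relative). Generator points
receive a seeded 1e-9 jitter so cocircular degeneracies resolve
deterministically.

Relaxation stops when the maximum centroid displacement falls below `tol`
(default 1e-3 in disk-radius units) or after `max_relax_iters` (default
100). The displacement plateaus near 5e-4 at n = 400 because cell-topology
flips keep injecting small rearrangements; at the default settings the
area coefficient of variation is ~0.07, within the ≤ 0.10 equal-area
target. The relaxed mesh approximates an energy-minimized foam; we do not
reproduce a surface-tension-based evolution with elevated rim tension, so
rim cells are slightly less compact than a foam model would make them — a
known, cosmetic limitation.

Two cells are adjacent iff their polygons share an edge of positive
length. The normalized radius divides each centroid's distance from the
island center by the 95th-percentile centroid distance (clipped at 1),
matching the convention used for imaged islands; the boundary region is
radius ≥ 0.95 and the interior is its complement. `on_rim` flags cells
whose polygon touches the disk edge (the "not surrounded by neighbors on
all sides" rule used in image analysis).

## Mechanical fields

Per-cell traction, cell–cell force and E-Cadherin are radial profiles:

- traction(r) = t_interior + (1 − t_interior)·exp((r − 1)/lam_t), i.e. an
  interior plateau (default 0.2 after max-normalization) with an
  exponential rise to 1 at the rim;
- ecad(r) = e_interior + exp((r − 1)/lam_e), flat interior with a rim rise;
- cellcell(r) = c_max·(1 − traction(r)), the inverse of traction, high in
  the interior and vanishing at the rim. The inverse is taken as a
  complement rather than a reciprocal because a reciprocal diverges at low
  traction.

Decay lengths default to 0.05 radius units so the transitions occupy the
r ∈ [0.9, 1] band where the fate bifurcation is observed; the observed
profiles constrain the shape ("exponential at the boundary") but not the
amplitudes, so the plateau levels and lengths are exposed as
`FieldParams`. Measured traction can replace the analytic profile: a CSV
of (replicate, radius, stress) rows is max-normalized by the mean of the
per-replicate maxima, binned into 20 radial bins, replicate-averaged and
interpolated to the cell radii.

The fields couple into signaling through S_i = ECAD_i·Traction_i
(facilitates trans-activation; maximal at the rim) and C_neighbor,i =
Σ_j ECAD_j·CellCellForce_j over the adjacency neighbors (inhibits it;
maximal in the interior). The force-free model replaces the multiplier
S/(0.1 + C) by 1 and C by 0, recovering unmodulated lateral inhibition.

## Signaling model and parameters

The five-species ODE system per cell is given in the README. Fixed
structural choices:

- Neighbor abundances are cumulative sums, not means.
- The NICD equation uses symmetric saturation denominators, 1 + T_D and
  1 + T_J; the variant with the Dll1 trans term inside the Jag1
  denominator is available via `eq2_printed_denominator` for comparison.
- The receptor decay term applies to N_R (the only receptor species).
- All decay rates are 1, so time is measured in species lifetimes;
  concentrations are arbitrary units.

Interaction strengths are the ligand-role parameterization: k_cD = 22,
k_tD = 0.3 (Dll1 predominantly cis-inhibitory), k_tJ = 10 (Jag1 purely
trans-activating), Hill exponent h = 2, softening constant 0.1.

The production rates are free parameters of the model; we calibrated them
by grid search against the qualitative regime set that defines the
system: (i) the force-free model must sit in the lateral-inhibition
(salt-and-pepper) regime, (ii) the full model must confine Notch targets
to the rim with a ≥ 2× boundary/interior contrast, (iii) Dll1 knockdown
must raise and Jag1 knockdown abolish rim activity, and (iv) the
growth-factor responses must have the observed geometry. High symmetric
rates (all betas ≈ 5) saturate both trans-activation Hill terms and give
a homogeneous high state; the defaults betaN = 2, betaD = 3, betaJ = 0.3,
betaNICD = 5 keep T_J unsaturated and make the wild-type rim weakly
active through cis-dominant Dll1 suppression, which is what lets the
Dll1 knockdown de-repress it (the boundary-rate increase seen
experimentally). These regimes are robust to the integration seed and to
moderate (±30%) parameter perturbation but the individual defaults are
declared calibration choices, not measured quantities.

Initial conditions: D, J ~ Uniform(0, noise_amp) with noise_amp = 0.3
(one-tenth of betaD — the ligand noise is the symmetry-breaking seed of
the pattern), N_R = betaN, NICD = NT = 0, all drawn from a seeded RNG.

Integration uses an implicit BDF solver (rtol 1e-6, atol 1e-9) with the
lattice's block sparsity pattern supplied for the Jacobian; the state is
species-major (5 × n). The horizon is t_end = 1000 with the default
n_out = 101 samples; steady state is reached well before (the trajectory
is flagged converged when max|rhs| < 1e-6·max|state| + 1e-9). Species are
not clamped; solver tolerances keep negative excursions below 1e-9 and
NT is floored at 0 inside the Hill terms so fractional exponents stay
defined.

## Perturbation scenarios

Scenarios are declarative flags resolved before simulation: Dll1/Jag1
knockdowns scale betaD/betaJ by 1 − 0.75; the E-Cadherin knockdown scales
the ECAD field by 1 − 0.70 uniformly (the traction and cell–cell force
fields are left intact, consistent with the observation that force
gradients persist under E-Cadherin loss, presumably via other cadherins).
EGF (egf = 1) and TGFβ2 (tgfJ = tgfD = tgf = 2, b = d = v = 1) activate
their equation variants; the magnitudes were chosen together with the
production-rate calibration so that EGF raises Notch targets with the
boundary restriction retained while TGFβ2 extends them inward and its
effect is blunted by Dll1 knockdown (the induction term is
Dll1-dependent). Combined EGF+TGFβ2 treatment is not modeled. The battery
enumerates 4 genotypes × 3 treatments = 12 conditions.

## Quantification

- Radial profiles: 20 equal bins on [0, 1] (the boundary band is exactly
  the last bin), per-bin mean with a normal-approximation 95% CI
  (mean ± 1.96·SE). Empty bins carry n = 0 and NaN.
- Region statistics: boundary (r ≥ 0.95) vs interior means, their ratio,
  and a two-sided Wilcoxon rank-sum (Mann–Whitney) p-value using the
  exact null distribution for small tie-free samples.
- Salt-and-pepper metric: Moran's I on the adjacency graph with binary
  weights; negative values indicate neighbor alternation.
- Heatmaps: polygon-filled fields with a perceptually uniform colormap.

## Synthetic experiment generator

The generator emulates the per-cell segmented readout of imaged islands:
radii follow the area-uniform disk density; OPN/HNF4α positivity is
Bernoulli and Hes1 speckle counts Poisson, with rates interpolated
logistically between interior and boundary values centered at r = 0.95.
Defaults: OPN 1% interior / 10% boundary, HNF4α 20% / 4%, Hes1 mean 5
with a 2-fold boundary increase, 50 islands × 400 cells. The interior OPN
and boundary HNF4α rates are reported experimentally only as bounds
(< 2% and < 5%); 1% and 4% are our point choices. The logistic steepness
defaults to 200 per radius unit (transition width ~0.02): the transition
must be substantially narrower than the 0.05-wide boundary band,
otherwise the band-averaged positivity under-represents the plateau rate
that the generator is parameterized by.

The generator draws cells independently: it reproduces radial statistics
but has no neighbor correlation, island-to-island biology, segmentation
error or intensity distributions. Tests that pass on these tables
therefore validate the quantification pipeline and the radial structure,
not performance on real imaging data.

## Problem sizes and determinism

Analyses and acceptance checks run at the study scale: 400-cell islands,
horizon 1000, 50 × 400 synthetic cells. A full scenario battery takes
~1 minute on one CPU and a single island simulation ~3 s. Every random
draw (lattice seeding, initial-condition noise, synthetic tables) is tied
to an explicit seed; the workbench fans one global seed out to per-stage
seeds via SHA-256 so stages are independently reproducible, and reruns
are byte-identical.

## Known limitations

- Cells are static: no motility, division or growth (EGF's proliferative
  effect on cell number is not modeled — only its signaling effect).
- Mechanics is prescribed, not solved: the traction / cell–cell force
  profiles are inputs, so force rebalancing after perturbations (e.g. the
  elevated traction seen in Dll1 KD) is not emergent.
- The model is deterministic ODE; no transcriptional noise beyond the
  initial conditions.
- NT is a lumped readout; distinct Notch targets with different response
  magnitudes (Hes1's modest 2-fold vs OPN's strong contrast) are not
  resolved.
- Simulated NT is in arbitrary units; comparisons with data are therefore
  rank- and ratio-based, never absolute.
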