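# Methods

## The adaptive bias

The sampler maintains a mollified sampling mass `S` on a discretized grid
over collective-variable (CV) space (1D or 2D; each dimension optionally
periodic). The repulsive bias applied to the dynamics is the flooding-type
log form

    V(cell) = b · kT · ln(c · S(cell) + 1)

with three tunable parameters:

* `b` ∈ (0, 1) — bias fraction. Binding setups use 0.9; dihedral setups 0.8.
* `c` ≥ 0 — deposition rate per dynamics time step. Binding setups use
  0.005/δt and dihedral setups 0.1/δt; the desk-scale toys here use larger
  values (up to 1/δt) because they must flood kcal/mol-scale wells within
  ~10⁵ steps rather than 10⁹. `c = 0` disables the potential entirely (the
  unbiased limit).
* `α` — mollifier half-width in grid bins. Each visit deposits a compact
  quartic bump `w(r) ∝ (1 − (r/α)²)²` over bins `−α..α` (product form in
  2D), normalized to unit mass. The bump is C¹ at its support edge, so the
  accumulated density — and hence the interpolated bias force — is smooth.

### Importance-weighted deposition

Each deposit is scaled by `exp(V_center/kT)`, the inverse Boltzmann factor
of the bias at the deposit center (the update used by self-healing
umbrella sampling). This makes `S` an estimator of the *unbiased* visit
density, which is what makes the free-energy estimator

    F̂ = −V / b   (min-shifted over visited cells)

asymptotically exact: in the quasi-stationary state, sampling follows
`p ∝ exp(−(U+V)/kT)`, so weighted deposits grow every cell's `S` at a rate
proportional to `exp(−U/kT)` and `V → −b·(U − const)`. With *unweighted*
counts the same algebra gives the fixed point `V = −b/(1+b)·(U − const)`,
i.e. `F̂` would systematically underestimate the landscape by the factor
`1 + b` (almost 2 at b = 0.9). The choice is pinned empirically by the
double-well recovery test, which measures `F̂` against the analytic
landscape to 0.3 kcal/mol RMS.

### Overfill protection

Every deposit is additionally gated by

    g = clip(1 − V_center / flim, 0, 1),

a linear ramp that smoothly saturates the bias at the fill-limit `flim`
(kcal/mol) and prevents the bias from driving the system over unphysical
barriers (through a receptor's secondary structure, in the method's
production use). Every kernel increment is additionally clipped per cell
at the fill-limit, so `V ≤ flim` holds in every cell at all times — also
for cells receiving only the tails of deposits centered elsewhere.
Interpolated bias energies are clipped at `flim` with zero gradient where
clipped. `flim = 0` disables deposition (bias off).

Because cells at the cap stop growing while cells below it continue, the
landscape estimate slowly degrades once the range of `F` over the sampled
region approaches `flim/b`; fill-limits should sit comfortably above the
barriers of interest but runs should not be continued long past the onset
of saturation. This finite-time trade-off is intrinsic to capped flooding
and is what the fill-limit calibration scan (below) navigates.

### Grid numerics

* Bin width per dimension is exactly `(hi − lo)/bins`; a 480-bin grid over
  0–60 Å has 0.125 Å bins.
* The bias is evaluated continuously by multilinear interpolation of cell
  values at cell centers, with the analytic gradient of the interpolant as
  force. Outside the range of a non-periodic dimension the edge value is
  returned with zero outward gradient; deposits beyond the range clamp to
  the edge cell and are counted (`clamped_deposits`).
* Periodic dimensions wrap indices modulo the bin count, in deposition,
  interpolation and basin analysis.
* Checkpoints (`.mabp`) are a one-line JSON header (geometry, parameters,
  counters, format version) followed by the little-endian float64 weight
  block.

## Collective variables and restraints

The ligand-binding construction uses two RMS-distance CVs: the ligand is
split into two atom groups and each group's CV is

    cv = sqrt( (1/n) Σᵢ ‖xᵢ − r‖² )

against a *dynamic reference* `r`, the center of geometry of a receptor
Cα selection recomputed every evaluation. A single-point reference admits
no superposition, so no fitting is involved. Gradients follow the chain
rule, including the reference's dependence on receptor coordinates, so
the total CV gradient sums to zero (no net force injection). The gradient
is singular at cv = 0 and defined as zero there.

A periodic torsion CV (four atoms, standard atan2 convention, mapped to
[0, 2π)) serves dihedral landscapes; its analytic gradient is validated
against central finite differences, as are all CV gradients.

Restraints are flat-bottom harmonics, zero inside and C¹ at the
boundaries: a cylinder (default radius 18 Å, axis +z — the membrane
normal in the receptor setups, configurable) centered on the geometric
center of the two CV reference points, and a per-CV cap (default 22 Å).
Force constants default to 10 kcal/mol/Å². The restraint force on the
ligand center of geometry is distributed uniformly over the ligand atoms.

## Dynamics

BAOAB-discretized Langevin dynamics in an AKMA-like unit system (Å,
kcal/mol, ps, amu; 1 kcal/mol = 418.4 amu·Å²/ps²). The total force is
`−∇U − (∂V/∂cv)·∇cv − ∇(restraints)`, with one deposit per step at the
current CV point. Runs are pure functions of `(system, config, seed)`:
identical inputs reproduce bit-identical trajectories, and a run with the
bias disabled consumes the random stream identically to an unbiased run,
so the two coincide exactly — the strongest form of the unbiased-limit
check. Constant volume only; frozen particles (the receptor dummies) are
excluded from integration. Coordinates beyond 10³ Å abort with a
blow-up diagnostic.

An external engine can couple to the bias through
`dynamics.bias_and_restraint_forces` (give coordinates, receive bias +
restraint forces); no specific engine is bundled.

## Toy systems

Every shipped system has an analytically known free energy along its CVs,
making recovery error exactly measurable.

* `double_well`: U(x) = h(x²−1)², h = 2 kcal/mol by default; the primary
  accuracy oracle (recovery to 0.3 kcal/mol RMS over |x| ≤ 1.3 at
  kT = 0.6).
* `harmonic`: equipartition oracle, var(x) = kT/k.
* `cosine_well`: U(θ) = h(1−cos θ) on the periodic circle; the
  dihedral-mode stand-in (300-bin 0–2π grid, b = 0.8, c = 0.1, α = 5).
* `mueller_brown`: the classic three-well/two-saddle 2D surface scaled by
  0.04 so the wells span a few kcal/mol at kT ≈ 0.62.
* `host_guest`: a 3D binding toy. A 4-particle ligand chain (two 2-atom
  groups for the two-CV construction) diffuses above six frozen receptor
  dummy atoms that form the two dynamic reference selections. The pocket
  combines per-atom Gaussian wells pinned at a constructed bound pose
  (2.0 kcal/mol per atom, σ = 0.7 Å — the bound ensemble stays in one
  1 Å CV cell) with a wide COG capture funnel (2.0 kcal/mol, σ = 2 Å).
  The binding barrier is an *asymmetric* Gaussian gate ridge on the
  approach axis (8 kcal/mol at z = 2.5 Å; σ = 3 Å on the solvent side,
  0.8 Å on the pocket side): the wide solvent flank lets the adaptive
  bias climb the barrier cell by cell — against a narrow ridge the
  overfill gating leaves a standing bias deficit of 1–2 kcal/mol at
  never-visited cells and the flooding stalls — while the steep pocket
  flank keeps the ridge's tail from raising the pocket energy. A
  16 kcal/mol wall and a decoy well behind it form the spurious-escape
  channel an overfilled bias can breach; flat-bottom walls (ρ < 2 Å,
  −4.5 < z < 8 Å) bound the solvent region so unbiased runs stay finite.
  The event-monitor distance runs from ligand atom 1 (the
  protonated-amine analogue) to an anchor buried below the gate, so the
  4 Å bound threshold is reachable only from inside the pocket. The toy
  grid is 16×16 cells of 1 Å over 0–16 Å with α = 3 and c = 0.3; the
  calibrated fill-limit is 20 kcal/mol (above the ~17 kcal/mol unbinding
  barrier), with 0.5 kcal/mol as the "too low" reference.

## Event detection and calibration

Binding/unbinding events use a two-threshold hysteresis automaton: the
ligand becomes bound when the monitored distance drops below 4 Å and
unbound when it exceeds 10 Å; dead-zone values inherit the previous
state, so events strictly alternate and |bindings − unbindings| ≤ 1.
Series start in the unbound state (ligand placed in solvent),
configurable. Efficiency is (bindings + unbindings) per microsecond, with
a ratio helper for comparisons against a reference rate.

`flim_scan` automates fill-limit calibration: biased runs over a ladder
of fill-limits (plus matched unbiased references), tabulating per-seed
event counts and whether the seed-averaged landscape develops a basin
inside a declared target region. On the host-guest toy the scan
reproduces the calibration phenomenology: a very low fill-limit leaves
the binding barrier unflooded (no events); a calibrated one produces
binding and unbinding while the landscape minimum stays in the pocket's
CV cell; an excessive one buys more events at the cost of smearing the
landscape and opening the decoy channel.

## Landscape analysis

* Averaging: cell-wise mean of min-shifted replicate landscapes over the
  replicates that visited each cell; visited mask is the union; result is
  re-min-shifted. Unvisited cells are excluded from every statistic.
* Basin finding: local minima (no strictly lower visited neighbor;
   8-neighborhood in 2D, wrapping on periodic dimensions) below a depth
  threshold, expanded to the connected region within 1 kcal/mol of the
  minimum and reported as bounding boxes sorted by depth. Regions that
  span a periodic seam are merged and reported in unrolled coordinates
  (lo may be negative). Ties count as minima so discretized plateaus are
  kept; minima sharing a region collapse to one basin.
* Frame extraction: frames whose CV point lies in a closed box, reduced
  to the ligand atoms. An empty selection warns rather than errors.
* Pose clustering: DBSCAN (scikit-learn) over pairwise ligand RMSD
  *without* re-fitting, defaults eps = 0.7 Å and min_pts = 25 (counting
  the point itself). Frames should be receptor-aligned upstream
  (`align_frames`, Kabsch on a reference selection) — poses are only
  comparable in the receptor frame. The representative pose is the medoid
  of the largest cluster.
* Occupancy: on a 1D periodic landscape, basin occupancy is the
  Boltzmann-weighted cell sum `Σ_basin e^{−F/kT} / Σ_all e^{−F/kT}`.
  Membership is half-open `[lo, hi)` with wrap-around, so basins that
  partition the circle have occupancies summing to exactly 1. Occupancy
  is computed from the bias-derived landscape, not from raw biased visit
  counts, which are non-Boltzmann.

## Problem sizes and defaults in the shipped checks

The automated checks run the double-well recovery at 2×10⁵ steps per seed
(5 seeds), the host-guest calibration at 8×10⁴ steps per run (two
fill-limits × 5 seeds plus unbiased references) and the overfill-cap
assertion over 10⁶ random deposits; these sizes give comfortably
converged statistics for the toys' landscapes. kT defaults to
0.6163 kcal/mol (310 K).

## What the toys do and do not show

The synthetic systems exercise every algorithmic component — deposition,
capping, CV gradients, restraints, event counting, clustering — under
conditions where ground truth is analytic. They do not emulate solvent
friction memory, receptor flexibility, competing metastable poses, or
force-field error; passing tests demonstrate the correctness of the
machinery, not the accuracy of any particular receptor-ligand
application, whose CV construction and fill-limit must still be
calibrated per system.

## Known limitations

* Landscapes are 1D/2D only, matching the method's CV usage.
* The estimator degrades once the sampled free-energy range approaches
  `flim/b` (see overfill protection above); the scan reports, but cannot
  prevent, over-long runs at high fill-limits.
* Basin bounding boxes are axis-aligned; strongly curved basins are
  over-covered.
* The toy integrator is constant-volume with no constraints; the
  production-MD settings of real applications (barostats, SHAKE, PME)
  are out of scope and recorded only as configuration metadata.
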