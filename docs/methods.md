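# Methods

This note documents the models, conventions and numerical choices behind
`coilglobule`, and what its synthetic-data generator does and does not
emulate.

## Water models

Two rigid four-site parameter sets are built in:

| model | ε (K) | σ (Å) | q_H (e) | d_OM (Å) | μ (D) | ρ (g/cm³) |
|---|---|---|---|---|---|---|
| TIP4P/2005 | 93.2 | 3.1589 | 0.5564 | 0.1546 | 2.305 | 0.9979 |
| TIP4P/Ice  | 106.1 | 3.1668 | 0.5897 | 0.1577 | 2.426 | 0.993 |

The rigid internal geometry (r_OH = 0.9572 Å, θ_HOH = 104.52°) is the
standard TIP4P-family gas-phase geometry; it is stored explicitly on the
`WaterModel` so the dipole check is self-contained.  The M site carries
−2 q_H on the H–O–H bisector at d_OM from the oxygen; the molecule is
exactly neutral, so the dipole |Σ q_i r_i| is origin-independent.  For the
symmetric molecule it reduces to `2 q_H (r_OH cos(θ/2) − d_OM) · 4.803` D,
which reproduces the published μ of both models to better than 0.005 D —
the module's analytic validation surface.  ε, σ and ρ are carried as
metadata only: no energetics are computed anywhere in the package, and
reproducing the liquid density would require simulation.

Units: this module keeps Å and e (matching the parameter table); everything
else in the package uses nm internally.

## Structure handling

Only text formats are supported: GRO (nm) and multi-model PDB (Å, converted
on read).  Boxes must be orthorhombic; triclinic input is rejected loudly.
A TSV *topology sidecar* carries what the coordinate formats do not: per-atom
role (backbone_C, amide_N, amide_O, methyl_C, water_O, …), mass, Bondi
radius, residue index and the bond list.  Roles are assigned from atom names
through an explicit, editable mapping rather than element inference, so
synthetic and external naming schemes can coexist.  Water residue numbers
are reassigned by grouping O,H,H in file order on read, because fixed-width
residue fields overflow in large boxes.

Coordinates are treated as wrapped.  Analyses that need a whole chain call
`unwrap_polymer`, which walks the polymer bond graph and shifts atoms by
lattice vectors so each bonded pair sits at its minimum-image separation
(idempotent; a disconnected bond list is an error).  All pair criteria —
hydrogen bonds, shell membership — use minimum-image distances.

## Observables

**R_G** is the mass-weighted radius of gyration of the unwrapped chain.

**SASA** uses the Shrake–Rupley construction with a 0.14 nm probe and Bondi
radii fixed to H 0.120, C 0.170, N 0.155, O 0.152 nm.  Hydrogens are
included as surface atoms (consistent with an all-atom chain model); waters
are excluded both as surface and as occluders.  Sphere points come from a
deterministic Fibonacci (golden-angle) lattice, 960 points per atom by
default: the estimate is reproducible bit-for-bit and converges to the
two-sphere closed form `4πR(R + d/2)` within 1 % at that count (doubling
the count moves it by < 0.5 %).

**Hydrogen bonds** follow the geometric criterion: donor–acceptor distance
strictly below 0.35 nm and H–donor–acceptor angle strictly below 30°.  The
angle is measured at the donor between the D→H and D→A vectors (the
convention of the common trajectory tools); both thresholds are fields of
`HBondCriterion` and configurable.  Donors are amide nitrogens (via their
amide hydrogen) and water oxygens (via both hydrogens); acceptors are
carbonyl oxygens and water oxygens.  Donor–acceptor pairs within one
residue/molecule are excluded: an amide nitrogen and its own carbonyl
oxygen are 1,3-neighbours and a water cannot bond itself.

## Hydration statistics

A water is *hydrophilic* when its oxygen lies within 0.35 nm of any amide
N/O and *hydrophobic* when within 0.55 nm of any methyl carbon.  The
categories may overlap; the first shell is their union with each water
counted once, which keeps the hydrophobic fraction `F = |phobic|/|shell|`
in [0, 1] by construction.  *Bulk* is the complement of the shell — the
source analysis contrasts only shell and bulk, so no intermediate zone is
defined.  Frames with an empty shell are flagged and excluded from F
distributions rather than propagating a division by zero.

Water–water connectivity in a domain counts **unique** hydrogen-bonded
molecule pairs with both partners inside the domain, divided by the domain
size.  Counting bonds once (not once per participant) matches the scale of
published per-molecule shell/bulk values (~1.3–1.8), which are roughly half
the per-participant counts the same criterion yields.  Bonds straddling the
shell/bulk boundary are excluded from both domains and reported separately
(`n_cross_bonds`), since their attribution is a convention, not a
measurement.

## Transition fits and classification

Temperature series are fitted with the symmetric four-parameter Boltzmann
sigmoid; for this family the inflection value equals the plateau midpoint
`(A_coil + A_glob)/2`, which is exactly how the classification cutoffs are
derived.  Fitting is bounded least squares with deterministic
initialisation (plateaus from the endpoint means, midpoint at the steepest
finite difference, width = span/10), inverse-variance weighting by the
per-point SD whenever all SDs are positive (configurable), and explicit
failure modes: fewer than 4 points, a flat series, non-convergence, or a
width exceeding twice the data span all raise a no-transition error instead
of returning a junk fit.  The midpoint is constrained to the data range
±10 K.

The transition temperature is the arithmetic mean of the R_G and SASA
midpoints.  Its uncertainty is the larger of (a) half the absolute midpoint
difference and (b) the standard error of the mean propagated from the two
fit errors — the published values quote a ± without a formula, so this rule
is ours and is stated as such.

Classification: *coil* if mean R_G ≥ the R_G cutoff (ties go to coil, since
the globule rule is strictly "smaller than"); otherwise *globule*;
a globule with mean hydration ≥ 12.5 waters per repeating unit (tie
inclusive) is a *hydrated globule*.  The package defaults are the published
cutoffs (1.2 nm, 12.5); the pipeline can instead derive both from its own
sigmoid fits, which is what synthetic data require, since a geometric chain
model has no reason to share the published plateau values.  Per-pressure
phase boundaries are reported as the midpoint between the warmest coil and
the coolest globule; with all points on one side the boundary is marked
unresolved.  A sensitivity rerun with an alternative R_G cutoff (default
0.1 nm lower) lists exactly the points whose labels change — necessarily
those with cutoff_alt ≤ R_G < cutoff.

## Synthetic-data generator

The generator produces *geometric* configurations with known ground truth;
it has no force field, no Boltzmann sampling and no dynamics.

**Repeating unit.**  A 19-atom acrylamide-type template: backbone CH₂–CH,
then C(=O)–NH–CH(CH₃)₂, i.e. exactly 1 amide N, 1 amide O and 2 methyl
carbons per unit, with chemically sensible bond lengths (C–C 0.153, C=O
0.123, C–N 0.134, N–H 0.101, C–H 0.109 nm).

**Chain growth.**  The backbone is a persistent self-avoiding walk grown
residue by residue (step 0.153 nm); side groups are attached with a random
dihedral and a random mirror reflection per unit, which stands in for
atacticity at the level the analyses can see (methyl positions), not at the
dihedral-stereochemistry level.  A `compactness` control in [0, 1] lowers
the step persistence and adds a centroid attraction: 0 gives extended
conformers (R_G ≈ 2.4 nm for the 30-mer), 1 collapsed ones (R_G ≈ 0.95 nm).
No two heavy atoms more than four bonds apart come closer than 0.25 nm;
placement failures retry with local backtracking, then restart (relaxing
the attraction for pathological seeds), and finally raise an error echoing
the seed.

**Solvation.**  Water oxygens go on a jittered cubic lattice at the target
density (0.997 g/cm³ default); sites within 0.24 nm (minimum image) of any
solute atom are dropped, so the count is the ideal `ρL³N_A/M_w` minus the
excluded sites.  Hydrogens use the rigid model geometry with random
orientations — realistic H-bond statistics are *not* attempted, only
well-defined ones.  The solute can optionally be rotated onto the box
diagonal, the standard trick for fitting an extended chain into a cubic box.

**Ensembles.**  Each (T, P) state point draws frames from a two-state
mixture: globule with probability `1/(1 + exp(−(T − T_C*(P))/w))`, coil
otherwise, plus Gaussian noise (SD 0.05) on the compactness.  Because state
populations mix linearly, the ensemble mean of *every* conformational
observable — R_G, SASA, shell occupancy — follows a sigmoid in T with the
same midpoint, which is the statistical structure the transition fits
assume and the reason a recovery test is meaningful end to end.  (A
continuous compactness schedule was rejected: the compactness→R_G and
compactness→SASA maps are nonlinear in different regions, so each
observable would carry its own shifted apparent midpoint.)  Defaults are
desk-scale study conditions: 30 residues, 278–308 K every 5 K, width
2.5 K, 50 frames per state point, 4 nm box (~2100 waters per frame).  The
4 nm default is the smallest box in which the hydration-shell contrast
between coil and globule states clearly exceeds its own frame noise; in a
3 nm box the extended chain's periodic self-crowding washes it out.  The
full-size 8.5 nm box (~20,400 waters) is generatable and is used where the
extended chain must be crowd-free, e.g. the hydrophobic-fraction check.
Every frame re-solvates the chain independently, so shell occupancy tracks
the chain state purely geometrically; a `shell_water_boost` placement-bias
hook exists but defaults to off.  All randomness derives from
`(seed, pressure index, temperature index, frame index)`, and the manifest
records spec, truths and seeds sufficient to regenerate the files byte for
byte.

**What passing tests show — and don't.**  The generator validates the
*analysis machinery*: geometry kernels against oracles, fits against known
midpoints, classification logic against its own rules.  It does not emulate
force-field energetics, water structure (orientation correlations, real
H-bond networks), residence dynamics, or the published trajectory-derived
numbers (transition temperatures of specific water models, shell/bulk
connectivity values); those require the original microsecond-scale
trajectories and are explicitly out of scope.

## Pipeline conventions

The analysis window defaults to the last third of each trajectory — the
generic analogue of analysing the final 100 ns of 300 ns runs — and is
configurable as a fraction or frame range (synthetic ensembles, whose
frames are i.i.d., are typically analysed with `window = 1.0`).  The
reference pressure for transition fits defaults to the lowest pressure
present.  Outputs (per-frame TSVs, summary, fits, phase map, boundaries,
provenance JSON with a config hash) are a pure function of inputs and
configuration; reruns are byte-identical.

## Known limitations

* Orthorhombic boxes only; no binary trajectory formats; no velocities.
* The hydrated-globule region of a synthetic phase map depends on the
  derived hydration cutoff, whose plateau contrast is geometric, not
  thermodynamic — treat synthetic hydrated-globule labels qualitatively.
* SASA is O(atoms × points × neighbours); ~0.3 s per 30-mer frame at the
  default 960 points.
* `estimate_tc` reports an infinite uncertainty when a fit is exactly
  determined (4 points, 4 parameters); supply more temperatures for a
  meaningful error bar.
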