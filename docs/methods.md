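# Methods

This note records the models, conventions and numerical choices behind
`metadesk`, and what the synthetic test systems do and do not establish.

## Units and conventions

Lengths in nm (Å accepted at the PDB boundary and converted on read),
energies in kcal/mol, time in ps, temperatures in K, angles in radians.
k_B = 1.987204×10⁻³ kcal/mol/K; the Eyring prefactor k_B·T/h is ≈ 6.25×10¹²
s⁻¹ at 300 K. Atom indices are 0-based internally; residue indices are
1-based as in PDB files.

## Collective variables

RMSDs are computed after optimal superposition on the CV's own selection
(Kabsch on centered coordinates, no mass weighting; degenerate selections —
fewer than three atoms or a collinear set — are rejected). ΔRMSD is
rmsd-to-inactive minus rmsd-to-active, so the inactive basin sits at negative
values and swapping the endpoints negates the value exactly. The gradient of
a superposition RMSD treats the optimal rotation as locally constant; its
first-order variation vanishes at the optimum, and the test suite holds the
analytic gradients of all differentiable CVs to within 10⁻⁵ relative error of
central finite differences (step 10⁻⁶ nm).

ΔRMSD is a metric-difference coordinate: by the triangle inequality its value
is bounded by ±rmsd(inactive, active), and the bound is attained on the ray
through the second reference. A steered pull to the extreme value therefore
identifies the target structure only through the path taken, not through the
final CV value alone (see the steering notes below).

COM groups use the unweighted (geometric) centroid by default, with mass
weighting behind a flag; the COM-torsion gradient distributes each
center-point gradient over the group's atoms with the COM weights. Dihedrals
follow the IUPAC sign convention with range (−π, π].

The antisymmetric stretch is d(b, a) − d(b, c) for central atom b; it grows
positive as b migrates toward c. For the phosphoryl-transfer coordinate the
package follows the field's O–P–N argument order, under which the
transition-state fixture (P–O 0.217 nm, P–N 0.253 nm) evaluates to −0.036 nm.
The literature's prose convention ("negative once transferred") is ambiguous
about the bracket order; the formula above with the argument order fixed at
the call site is the package's convention.

Coordination counts use a hard cutoff (default 0.25 nm for Mg–O): ligand
counts are integers by construction, which is what the analyses consume.
Smooth switching functions are out of scope.

## Sampling

The integrator is Euler–Maruyama overdamped Langevin. It is a stand-in for
thermostatted molecular dynamics: the package's object of study is the bias
and free-energy machinery, not force fields. Temperature defaults to 300 K;
the timestep must keep the per-step mobility (Δt/γ_f) small against the
stiffest curvature of the landscape (mobility × curvature ≲ 0.5, or the
sampled distribution at steep flanks is visibly distorted).

Well-tempered metadynamics follows the standard protocol: every `pace` steps
each walker deposits a Gaussian of height h0·exp(−V(s)/((γ−1)k_B·T)), where V
is the bias already present at the walker's CV value. All walkers share one
bias; deposition rounds are synchronized and ordered by walker id, with each
walker seeing the hills laid down earlier in the same round, which makes
multi-walker runs fully deterministic given the per-walker seeds (spawned
from one run seed via `numpy` SeedSequence when not given explicitly).
Defaults (h0 = 0.3 kcal/mol, σ = 0.1 CV units, pace = 500 steps, γ = 10) are
typical well-tempered practice, not values taken from any specific study, and
are all configurable.

Bias evaluation during dynamics uses a regular-grid cache when a grid is
supplied: each hill is accumulated onto the grid once and lookups are
multilinear interpolation, making the per-step cost independent of the hill
count (points outside the grid fall back to the exact sum). FES
reconstruction never uses the cache: F(s) = −(γ/(γ−1))·ΣV_hills(s) is
evaluated from the hills on the analysis grid, then shifted to min 0. Hills
are truncated at 5σ in every dimension, a relative error below
exp(−12.5) ≈ 4×10⁻⁶ per hill. As γ→∞ the estimator reduces to the
non-tempered −ΣV.

### The double-well recovery experiment

The standard self-check samples the symmetric quartic double well
U(x) = 3·((x)² − 1)² kcal/mol (barrier 3, minima ±1) with four shared-bias
walkers, γ = 10, h0 = 0.3, σ = 0.1, and 5×10⁴ steps per walker (2×10⁵
total), then compares the reconstruction with the exact surface over the
region F ≤ 5 kcal/mol. Protocol numerics chosen for this experiment: Δt =
0.01 ps at friction 1 ps⁻¹ (mobility × well curvature ≈ 0.24), hill every 10
steps (the budget then spreads 2×10⁴ small deposits over the run rather than
a few hundred large ones), walkers started staggered across both basins, and
one-sided harmonic walls (k = 30 kcal/mol) at ±1.7 CV units to keep bias out
of the steep quartic tails — the usual region-of-interest confinement.
Under this protocol the RMS error is 0.06–0.20 kcal/mol across seeds,
against an acceptance bound of 0.3.

### Steered pulls

The moving harmonic restraint advances linearly over the schedule; the
reported work accumulates the discrete Jarzynski increments
U_spring(x_i, c_{i+1}) − U_spring(x_i, c_i). A quasi-static pull across a
barrier performs work at least the free-energy difference (second law),
which the tests verify within thermal noise.

Endpoint recovery on the two-domain bead model (pulling ΔRMSD from the
inactive to the active value) requires two ingredients the bare model lacks:
internal rigidity — supplied by an intra-domain elastic network whose
equilibrium lengths come from the inactive conformation and which is exactly
at rest in both endpoints, since each domain moves rigidly between them —
and suppression of thermal drift along the soft rigid-body modes orthogonal
to the pulled coordinate (the network does not restrain them, and nothing in
the potential prefers the active placement among equal-ΔRMSD placements).
The pull is therefore run cold (0.5 K default), where the gradient flow
tracks the minimal-motion path and lands within 0.01–0.04 nm of the active
reference; at ordinary temperatures the same pull reaches the right ΔRMSD
but wanders sideways on the constraint manifold, exactly as the metric
argument above predicts.

## Free-energy post-processing

Marginalization uses bin-midpoint quadrature in the log domain
(`logsumexp`), so deep wells cannot underflow, and renormalizes to min 0;
adding a constant to the input surface changes nothing. Reference marginals
of the synthetic 2D landscapes are computed over the same finite CV domain by
composite Gauss–Legendre quadrature (10⁴ nodes, machine precision for these
smooth integrands) so sampled and reference marginals share a domain
convention.

State finding smooths with a centered moving average (default 3 bins, 1
disables — metadynamics grids are noisy), takes interior local minima
(plateaus report their leftmost bin), and prunes by persistence: a basin
survives if the lowest pass separating it from any strictly lower point is at
least `min_depth` above it. Barriers between adjacent surviving minima are
the maximum of the smoothed profile on the connecting interval, argmax ties
toward the lower CV value. Endpoint bins are not minima, so a monotone
profile yields an empty state set.

Convergence is monitored as RMS(F_t − F_final) over the bins where the final
free energy is at most a threshold (default 10 kcal/mol), each F_t
reconstructed from the hills deposited by time t; the series ends at exactly
zero.

Clustering is GROMOS leader clustering on pairwise superposed RMSD:
repeatedly take the frame with the most neighbours within the cutoff as a
centroid (ties to the earliest frame), remove the cluster, recount.

The energy ledger anchors each stage's reactant level at the previous
stage's product level; stages may be (ΔG‡, ΔG) summaries or full 1D profiles
(whose first/last bins define the levels — the two forms are interchangeable
because composition only consumes the node energies). The overall barrier is
the composed profile's peak relative to the first reactant, and per-stage
peaks from the global reactant are also reported, so both the composed
maximum and any single-stage reading can be reproduced. The Eyring
conversion uses transmission coefficient 1.

## Contact analytics

A contact is any heavy-atom pair between two residues within the cutoff
(0.45 nm default); per-residue OR-aggregation matches residue-level maps.
For intra-set maps, sequence neighbours within ±1 (same chain) are excluded
to suppress trivially bonded contacts (configurable). Salt bridges pair
Arg NE/NH1/NH2 and Lys NZ (His ND1/NE2 behind a flag) with Asp OD1/OD2 and
Glu OE1/OE2 at a 0.40 nm default cutoff and 0.5 minimum frequency — the
cutoff and threshold are package conventions, not literature-fixed values.
The domain rotation angle is the axis-angle magnitude of the optimal rotation
mapping the reference mobile domain onto the frame's mobile domain after
superposing the frame on the reference over the fixed domain; the COM
distance is measured in the frame itself and both are invariant to global
rigid motion.

## Synthetic data: what it shows and what it does not

Every generator is seed-deterministic and returns its ground truth. The bead
models are Cα-only pseudo-residues written as valid PDB-subset files, so the
pipeline runs on files end to end. Two-domain defaults emulate the geometry
of a sensor-kinase activation: a 57° rotation of the mobile domain about a
recorded axis with the inter-domain COM distance closing from 2.55 to
1.92 nm. Transition trajectories interpolate linearly in Cartesian
coordinates — adequate for CV and geometry testing, not a physical pathway.
Contact trajectories give every residue pair its own dedicated atom pair in
an isolated spatial cell, so per-frame contacts are exactly independent
Bernoulli draws of the prescribed probabilities. The toy reaction center
fixes the transition-state-like distances (P–O 0.217 nm, P–N 0.253 nm) and an
octahedral six-oxygen shell at 0.21 nm around the divalent cation.

Passing tests on these systems establishes the correctness of the machinery
— CV values and gradients, bias bookkeeping, estimator formulas, map and
census logic — under known ground truth. They do not establish force-field
realism, convergence behaviour on rugged high-dimensional landscapes, or any
biological conclusion; the headline energetics of real kinase activation
enter the package only as printed inputs to the energy ledger.

## Known limitations

Underdamped integrators, replica exchange, adaptive hills, smooth
coordination switching, mass-weighted RMSD, path CVs, 2D minimum-energy-path
tracing, reweighting estimators and block-error analysis are out of scope.
The PDB reader rejects altlocs and insertion codes outright rather than
resolving them. The Euler–Maruyama scheme has O(Δt) sampling bias; keep the
mobility–curvature product small as noted above.
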