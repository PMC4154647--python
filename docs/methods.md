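# Methods

## Coarse-graining and charges

Proteins are reduced to one bead per residue at the Cα position; each
nucleotide to three beads at the heavy-atom centroids of its phosphate
(P, OP1/OP2, O5′), sugar (C1′–C5′, O4′, O3′) and base (remaining heavy
atoms) groups, ordered phosphate–sugar–base along each strand.  Only
Arg/Lys carry +1e and Asp/Glu −1e on the protein; every phosphate bead
carries −1e.  5′-terminal nucleotides without phosphate atoms simply lack
the bead (logged); the ideal-helix fixture places phosphates on every
nucleotide, so the standard 14/16-mer primer/template substrate yields 90
beads and a total DNA charge of −30e.

## Contact maps and the two-basin merge

Native contacts use an all-heavy-atom criterion: two residues (or a
residue and a DNA bead group) are in contact when any heavy-atom pair is
within 4.5 Å, with sequence separation ≥ 4 for intra-protein pairs; r₀ is
always the native bead–bead distance.  For coarse-grained fixtures with no
atomic detail the criterion falls back to bead–bead distance against a
caller-chosen cutoff (8 Å by default in the toys).  An exact O(n²)
enumeration backs the k-d-tree implementation in the tests.

The two single-basin maps are merged into a union: pairs in both maps are
SHARED (r₀ from the bound structure — the functional complex defines the
binding-competent geometry), A-only pairs INTRA_A (r₀ from the apo
structure), B-only INTRA_B, and bound-complex protein–DNA pairs INTERFACE.
All four classes are simultaneously active in the Hamiltonian; because the
two basins' exclusive contacts cannot be satisfied at once, the union
encodes the double-basin landscape.  This contact-union scheme is one of
the two standard multi-basin constructions (the other couples whole-basin
energies exponentially) and is the simpler, fully force-consistent choice;
it is isolated behind the topology so it could be swapped.

Hinges are bonded terms whose native bend angle differs by > 15° or
torsion by > 30° between the basins; they store both reference values, and
the flagged residues (angle centre, dihedral central bond) must cover the
flexible linker for the merge to reproduce the intended dual-basin
flexibility.  Non-hinge terms take the base-basin (apo) value.

## Hamiltonian

In reduced units (lengths in Å, energies and temperature in the native
contact unit ε, k_B = 1, bead mass 1, time unit τ = √(mÅ²/ε)):

* bonds k_b(r−r₀)², k_b = 100 ε/Å² — stiff harmonic springs standing in
  for rigid constraints; the equilibrium ensemble is equivalent and the
  integration step is reduced accordingly (dt = 5×10⁻⁴ τ by default);
* angles k_θ(θ−θ₀)², k_θ = 20 ε/rad², with the sin θ singularity clamped;
* dihedrals K_φ[(1−cos Δφ) + ½(1−cos 3Δφ)], K_φ = 1 ε;
* native contacts ε_c[5(r₀/r)¹² − 6(r₀/r)¹⁰], ε_c = ε × strength;
* excluded volume ε(σ/r)¹² over all non-native, non-bonded pairs,
  σ = 4 Å — purely repulsive, so the non-native LJ column of the energy
  decomposition is non-negative by construction;
* Debye–Hückel U = C·B(κ)·q_iq_j·e^(−κr)/(ε_r r) over oppositely charged
  pairs (1-2/1-3 bonded neighbours excluded; rigid-DNA internal pairs
  dropped as a constant).  Restricting to opposite-sign pairs follows the
  model description; a switch (`include_like_charge_pairs`) restores the
  all-pairs variant.  κ comes from the monovalent-salt Debye length
  computed with physical constants at a reference 298 K and ε_r = 80
  (λ_D ≈ 9.6 Å at 0.1 M); C = 332.0636 ε·Å/e² treats ε as a
  kcal/mol-scale unit so a ±1 pair at contact range contributes ~1–2 ε,
  and B(κ) defaults to 1 — both configurable, since the model's absolute
  electrostatic scale is a calibration choice.

Truncation: contacts at 3r₀, repulsion at 3σ, electrostatics at 3λ_D, each
energy-shifted to zero at its cutoff.  Cutoffs are disabled (`None`) in
every closed-form and conservation test; the shift leaves a force
discontinuity at the cutoff that is negligible at these ranges.

Two knobs: `lambda_linker` multiplies the force constants of hinge
angle/dihedral terms inside the declared linker range, with their
reference geometry taken from `bias_basin` (A or B) — small λ is a floppy
linker, large λ a rigid one locked to the chosen basin.  `eps_B_scale`
multiplies only the B-exclusive contacts between the mobile recognition
domain and its B-state partner (`lf_f_contact_ids`), tuning how strongly
the bound conformation is favoured.  Component-wise tests pin both knobs
to exactly their declared term sets.

Forces are analytic throughout (the dihedral gradient uses the standard
two-normal formulation with translation-invariance closure) and verified
against central finite differences to ≲10⁻⁸ relative; frozen DNA rows are
identically zero.

## Dynamics, replica exchange, kinetics

The integrator is BAOAB splitting; with γ = 0 it reduces to velocity
Verlet, which is how the energy-conservation surrogate test runs (drift
< 10⁻⁴ ε over 10⁴ steps at dt = 8×10⁻⁶ τ).  Default γ = 0.25 τ⁻¹ and
dt = 5×10⁻⁴ τ correspond to the nominal 1 ps⁻¹ / 2 fs of an
all-atom-calibrated run under the documented unit conversion; both are
plain configuration.  A per-step displacement guard aborts with advice to
reduce dt rather than produce NaNs.

Replica exchange attempts neighbour swaps every `exchange_interval` steps
(alternating even/odd pairs), accepting with min(1, exp[(1/T_i − 1/T_j)
(E_i − E_j)]) and rescaling velocities by √(T_new/T_old) on acceptance.
The ladder is configuration (geometric spacing toward a 15–40 % acceptance
window is the usual tuning target); a single-temperature ladder reduces
exactly to plain MD with the same seed.

Kinetic ensembles spawn one child seed per run from the master seed
(`numpy SeedSequence`), so every record is reproducible in isolation and
no two runs share a stream.  Binding runs start from the apo conformation
rigid-body rotated to a uniform random orientation at a centre-of-mass
separation of native + 30 Å (rejecting poses within 4 Å of the DNA;
bounded retries).  Runs that never satisfy the stop predicate are flagged
censored and contribute the observation horizon — the largest observation
time — to the mean passage time, whose standard error treats censored
values as observations.  For one-bead fixtures the ensemble propagates all
walkers in lockstep with per-run noise streams, which is what makes
500-run passage ensembles a ~30 s computation.

## Analysis

A contact is formed when r < 1.2 r₀ (the community-standard formation
factor; configurable).  Q_iDNA runs over the interface set, Q_A over the
A-exclusive recognition-domain contacts, Q_iB over the B-exclusive set.
Conformational states: A if Q_A > 0.8 and Q_iB ≤ 0.05 (a continuous
coordinate cannot be exactly 0, so "= 0" is operationalized as ≤ 0.05);
B mirrored; I if both < 0.1; otherwise unassigned.  Binding stages are
cutoff surrogates for free-energy basins, with precedence BS > IS > EC >
US: BS at Q_iDNA ≥ 0.8; IS when the recognition-region (LF + linker)
interface fraction ≥ 0.6 while the core regions are unbound (< 0.1); EC
when any inter-chain bead pair is within 8 Å (or D_COM is inside the
native separation + 15 Å); US otherwise.  These thresholds are exposed in
the configuration; they reproduce the qualitative stage signatures
(encounter complexes carry contacts but Q_iDNA < 0.1) but are not claimed
identical to basin boundaries drawn on a free-energy surface.

WHAM is implemented binless over samples (coordinates + potential
energies per temperature): self-consistent offsets f_k solved by iteration
with log-sum-exp stabilisation (tolerance 10⁻¹⁰ on offsets here, well
inside the configured 10⁻⁷), then per-sample weights at any target
temperature for surfaces, populations and temperature scans.
Single-temperature input reproduces the raw-histogram free energy exactly
(the weights degenerate to uniform); non-overlapping neighbour energy
ranges raise an error naming the gap.  A separately written
histogram-based WHAM iteration serves as the cross-check oracle in the
tests.

The non-native ("cutoff") contact profile counts all inter-chain bead
pairs within 8 Å — native or not — averaged over frames and aggregated
per protein residue, per nucleotide, and per DNA bead kind.  Per-stage
energy tables restrict the decomposition to protein–DNA pairs
(native/non-native × electrostatic/LJ), which is why a dissociated
ensemble shows all four entries ≈ 0.

## Synthetic fixtures and oracles

The toy protein is three helical domains (F, T, LF) joined by a turn and a
charged 3-bead linker (~30–40 beads).  Basin B applies a proper torsion
about the middle linker bond: every bond and bend angle is bitwise
identical between basins and exactly one backbone dihedral differs by the
rotation, so the planted hinge is known exactly (the two central linker
residues).  The F domain is placed against the B-state LF pose by a
deterministic clash-free search, giving A-exclusive LF–T and B-exclusive
LF–F contact sets with clean separation (Q_A: 1.0 → 0.03, Q_iB: 0.05 → 1.0
between the references at the default 165° rotation).  Ground truth
(contact-class counts, hinge residues, charges) is computed by independent
brute-force enumeration inside the generator, not by the builder code
paths.  The ideal duplex is a parametric B-form-like helix (rise 3.4 Å,
twist 36°/bp) whose pseudo-atomic export places atom groups symmetrically
about each analytic centroid, making the coarse-graining round trip exact
by construction; it is a fixture geometry, not a claim about crystal
structure.

The 1D oracle problem is a quartic double well (with optional tilt and
harmonic y/z confinement that factorises out of every x-marginal).
Boltzmann populations come from trapezoid quadrature with a
refinement-convergence guard; mean first-passage times from the
Smoluchowski double integral with D = T/γ, valid in the overdamped regime
(the test settings use γ = 10 τ⁻¹ against barrier frequencies ≲1, where
the residual inertial correction is a few percent — inside the 15 %
agreement band).  Neither oracle shares code with the sampling kernels.

What the fixtures do *not* emulate: real contact-map topology and
cooperativity of a ~350-residue polymerase, sequence-dependent DNA
energetics, DNA flexibility (the duplex is rigid and frozen by
construction), or solvent beyond Debye–Hückel screening.  Passing tests
therefore certify the machinery — model construction, energetics, forces,
sampling statistics, reweighting, censoring rules — not biological
conclusions about any particular protein; runs on real structure pairs
use the same code paths via `dualbasin build`.

## Numerical choices and limitations

* Colinear angles are clamped (sin θ ≥ 10⁻⁸); degenerate dihedral normals
  likewise — no NaNs, at the cost of exact force accuracy only *at* the
  singular configuration.
* The topology text format prints floats with `%.17g`, so write/read
  round-trips are bit-exact.
* Trajectories are HDF5 with seed/temperature/config-hash attributes;
  analyses refuse trajectories whose config hash disagrees.
* Problem sizes in the test suite (30–70 bead toys, 10⁵-step ensembles,
  500-run kinetics) were chosen so the whole suite completes in a couple
  of minutes on one CPU while leaving every statistical check with
  3σ-level resolution.
* The full-system qualitative check (coexisting A/I in the unbound stage,
  B-dominated bound stage) requires the experimental apo and bound
  crystal structures as local files and cluster-scale sampling; the
  corresponding test runs the entire pipeline when those files are
  provided and reports a failure (not a skip) when they are absent.
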