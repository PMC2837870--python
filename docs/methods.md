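# Methods

## Reduced representation

A residue is represented by four pseudo-atoms: Cα, Cβ, side-chain center
(SC) and the midpoint of the virtual Cα–Cα bond. Cα positions live on a
cubic lattice of spacing 0.61 Å. The admissible virtual-bond set contains
every integer vector **v** with 29 ≤ |v|² ≤ 49, i.e. bond lengths of
3.29–4.27 Å around the canonical 3.78 Å. The window was found by brute
force as the integer window centered on (3.78/0.61)² ≈ 38.4 whose
enumeration yields exactly 800 vectors; the count, not the window, is the
anchor. (The window (28, 49) describes the same set: 28 = 4·7 is not a
sum of three squares.) Vectors are ordered lexicographically, which fixes
a stable 1-based id used by the geometry tables.

Cβ and SC positions are off-lattice, derived from the local frame of
three consecutive Cα's: Cβ sits 1.53 Å from Cα along the negative
bisector of the two flanking virtual bonds plus a fixed out-of-plane
component (weight 0.6 along their cross product) that encodes L-amino
acid handedness; the SC continues along the same direction to a
per-residue-type canonical distance (glycine: 0, i.e. SC ≡ Cα). Because
the two flanking bond vectors fully determine this geometry, the offsets
are memoized per (bond-id, bond-id) pair — an on-demand computed table
with plain-text serialization, rather than a shipped 800×800×20 file.
Chain termini copy the nearest interior residue's frame.

## Projection onto the lattice

The lattice is fine enough that protein-like Cα traces should project at
roughly 0.35 Å RMSD or better; the projection algorithm itself is: grid
search over 5³ rigid sub-lattice offsets of the input (each axis sampled
at k/5 lattice units); for each offset the chain is rebuilt bond-by-bond
taking the admissible vector that minimizes the cumulative squared
position error with a one-bond lookahead over the 12 best immediate
candidates. A cheap no-lookahead pass ranks the offsets and only the best
few are refined. Cost is O(N · 800) per offset; measured mean accuracy on
the synthetic suite is ≈ 0.26 Å. Disjoint scaffold segments flanking an
excised loop are projected jointly into one shared frame (same offset) so
the loop can bridge them on-lattice.

## Energy function

All parameters are surrogate values in reduced units (k_B = 1), shipped
as editable defaults (`EnergyModel`, YAML-serializable, `--ff` on the
CLI). The term structure, not the parameterization, is the contract.

* **Excluded volume** — +∞ sentinel if any non-bonded (separation ≥ 2)
  Cα pair < 3.3 Å or Cβ pair < 2.7 Å.
* **Generic short-range bias** — binned tables on r13 (3.6–7.6 Å, 20
  bins) and signed r14 (±11.5 Å, 30 bins; sign = handedness of the three
  bonds, with exactly coplanar windows counted right-handed so the sign
  is stable under rigid-motion floating-point noise). Gaussian wells at
  the helix band (r13 ≈ 5.43, r14 ≈ +5.05) and strand band (r13 ≈ 6.7,
  |r14| ≈ 10.1); the helix well exists only at positive r14, so a
  mirror-image helix scores strictly worse. Descriptors outside the
  table clamp to the edge bins.
* **Sequence-dependent short-range term** — the central residue of each
  window modulates the same bins through a three-class H/E/C propensity
  (helix formers AELMQKRH, strand formers VIYCWFT, rest coil), a
  Chou–Fasman-style scale.
* **Side-chain contacts** — square wells between SC centers at sequence
  separation ≥ 3: +2.0 inside 3.5 Å, −ε in 4.5–6.5 Å, 0 beyond. ε by
  residue-class pair: hydrophobic–hydrophobic 1.0, mixed 0.1–0.3,
  polar–polar 0.2, opposite charges 0.6 (wider well), like charges −0.3
  (net repulsive well).
* **Hydrogen bonds** — a Cα pair (separation ≥ 3) at 4.4–5.6 Å whose
  pair axis is near-perpendicular to both local chain tangents
  (|cos| ≤ 0.5) counts as a bond (−1.0); bonds adjacent in both partners
  (parallel (i,j),(i+1,j+1) or antiparallel (i,j),(i+1,j−1) registers)
  add −0.5 each. The geometric criterion and cooperativity rule are
  documented surrogates; no published quantitative form exists for them.
* **Restraints** — flat-bottom harmonic, `w · max(0, |d−d0| − tol)²`.

A numba-compiled kernel fuses all terms for the sampler's inner loop;
the pure-numpy term functions are the reference implementation and the
test suite asserts their equivalence to ~1e-13.

## Restraints

*Single-template mode*: candidate pairs are non-loop residues with
sequence separation ≥ 5 and Cα distance ≤ 12 Å; d0 is the observed
distance, tol 0.5 Å, weight 10 (strong — the scaffold moves during
sampling but is effectively pinned; evaluation superposes on the
scaffold regardless). Above 500 pairs a seeded uniform subsample is
kept; a compact ~100-residue scaffold yields several hundred restraints.

*Hybrid mode*: with k ≥ 2 equal-length template models, d0 is the
across-template mean, tol = max(0.5 Å, stdev), pairs with stdev > 3 Å
are dropped, and loop-region pairs are included — this is how external
models' loop conformations steer the sampling. With k identical
templates the derivation reduces to single-template restraints on the
shared pair set (asserted by tests).

*Loop-derived restraints* (benchmark recovery and the hybrid limiting
case) keep pairs down to separation ≥ 3: the short-range pairs are the
ones that actually encode a short loop's conformation; with the generic
separation-≥ 5 rule a 4-residue loop contributes no informative pair at
all. Weight 1 (the loop default).

## Sampling protocol

Moves and proposal weights: single-Cα 0.50 (re-placed among the exact
two-bond bridges between its neighbours), fragment re-growth of 2/3/4
residues 0.15/0.10/0.10 (random admissible growth with reachability
filtering and exact two-bond closure), rigid lattice shift of a 4–22
residue fragment 0.15 (junction bonds must remain admissible, else
auto-reject). Every proposal satisfies the chain invariant by
construction; hard-core violations reject through the +∞ energy.

Random loop insertion grows the excised range residue-by-residue with
uniformly random admissible bonds, filtered by (a) reachability of the
downstream anchor with the remaining bonds, solving the last two bonds
exactly via the bridge table, and (b) hard-core distance to placed
residues. On repeated closure failure the hard-core filter is relaxed
(loop-only, then none) before raising.

Replica exchange uses the standard criterion
min(1, exp((1/T_i − 1/T_j)(E_i − E_j))) between ladder neighbours, even
and odd pairs alternating. Annealing multiplies the whole equally spaced
ladder by a constant factor per macro-cycle, preserving the constant
temperature spacing; one snapshot of the lowest-temperature replica is
stored per macro-cycle. Each run is a pure function of its seed (one RNG
per replica plus a swap RNG, spawned from the master seed), and repeats
derive independent seeds from the same master.

Presets (all open protocol parameters; chosen for desk-scale problems):

| preset | replicas | T ladder | anneal | macro-cycles | sweeps/cycle |
|--------|----------|----------|--------|--------------|--------------|
| quick  | 5        | 1.0–2.0  | 0.95   | 20           | 25           |
| full   | 20       | 1.0–2.5  | 0.98   | 100          | 100          |

The quick preset exists because the full 20-replica protocol is not a
sensible test surface; it keeps a fixture case to ~15 s per run.

## Model selection and evaluation

The blind top model is the global medoid of the collated snapshots from
all repeats. Distances are loop-region Cα RMSDs after superposing each
snapshot's scaffold onto a common frame — the scaffold is near-identical
across snapshots and whole-chain distances would wash out loop
diversity (a `--cluster-on full|loop` knob exposes the alternative).
K-means clustering (k = 5 default) with per-cluster medoids is reported
diagnostically; in well-converged annealed runs the whole-trajectory
medoid is at least as good a selector as the largest cluster's medoid.
The "best" model (minimum loop cRMSD over snapshots) is a benchmark
oracle only; the blind path never reads native coordinates.

Loop cRMSD superposes all non-loop residues (Kabsch, proper rotations
only) and measures Cα RMSD over the loop; the loop endpoints belong to
the loop. Aggregation uses three length bins (4–6, 7–12, 16–25);
lengths falling in no bin are skipped with a warning. The paired
t-test on matched per-case columns uses the classic formula with n − 1
degrees of freedom and raises on zero-variance differences.

## Synthetic fixtures

The fixture generator emulates small single-domain proteins:
helix-loop-helix, beta-hairpin and three-helix topologies assembled from
ideal elements (helix: rise 1.5 Å, radius 2.3 Å, 100°/residue; strand:
3.3 Å rise with a 0.95 Å pleat) packed at realistic spacings (~10.5 Å
between helix axes, 4.9 Å between strands). Connectors are circular arcs
solved so every Cα–Cα chord equals 3.8 Å, bulging away from the core
(surface loops pack against the body rather than pointing randomly into
solvent), with small seeded jitter. Sequences are synthetic but
amphipathic: a heptad repeat (LESATKQ) giving ~30 % hydrophobic core
positions and serine connectors — roughly the composition of real small
helical proteins. An earlier all-hydrophobic design made the contact
term overwhelm every other signal, which is a force-field artifact real
sequences do not show.

What the fixtures do **not** emulate: side-chain rotamers, irregular
native loop conformations, crystallographic noise, long-range
electrostatics, multi-chain context. Passing the recovery test therefore
demonstrates protocol correctness (projection, restraint derivation,
sampling, selection, evaluation chained end-to-end), not predictive
accuracy of the surrogate force field on real proteins.

## Problem sizes and numerical choices

The shipped tests run the pipeline on 20–46 residue fixtures with the
quick preset and 2–3 repeats; the projection accuracy suite uses 50
traces of 20–80 residues. Tolerances: bit-exact reproducibility for
same-seed runs; 1e-9 for geometry oracles (Kabsch vs quaternion, term
additivity); Monte-Carlo acceptance rates to ±0.005 at 10⁵ trials.
Ties in medoid selection break to the lowest snapshot index. Degenerate
local frames (collinear bonds) fall back to a deterministic
perpendicular. Descriptors outside table ranges clamp to edge bins.

## Known limitations

* The force-field numbers are surrogates; absolute energies are not
  comparable to any published parameterization.
* Blind (scaffold-restraints-only) recovery of surface loops is limited
  by the surrogate force field's preference for packed conformations;
  loop-region restraints (hybrid mode) are the intended accuracy path,
  mirroring the method's comparative-modeling usage.
* Single chain only; no insertion-code arithmetic beyond identity; no
  all-atom reconstruction of the reduced models.
* The projection is greedy with lookahead, not globally optimal; its
  accuracy target is met empirically, not guaranteed.
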