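# Methods

This note documents the models, conventions and numerical choices behind
`tcrm`, and what the synthetic fixtures do and do not establish about real
crystal structures and instrument data.

## Coordinate model and conventions

Structures are heavy-atom only: the inputs this pipeline targets are
crystal structures at ~2.2–2.4 Å resolution, which carry no hydrogens, so
every computation (SASA, contacts, energies, H-bond detection) is defined
on heavy atoms.  Author residue numbering with insertion codes is the
public convention; internal indices are contiguous.  Alternate locations
collapse to the highest-occupancy conformer (ties: first in file), giving a
deterministic single-conformer model.  Waters are always removed; other
hetero residues are dropped unless requested.  PDB output is fixed-width
(3 decimals); mmCIF output emits shortest-round-trip float reprs so a
read–write cycle is bit-exact.

Role assignment (`partition_complex`) validates a chain-level partition
into TCRα / TCRβ / MHC heavy / β2m / peptide: roles must be disjoint, the
peptide 8–11 residues, and each TCR chain must contain an intrachain
disulfide (two CYS SG within 2.5 Å).  Full-length TCR chains contain both a
variable- and a constant-domain disulfide; the lowest-numbered pair is
taken as the variable-domain one, since the V domain precedes the C domain
in sequence.  Auto mode uses relative, letter-agnostic heuristics: the
peptide is the shortest 8–11-residue chain; the MHC heavy chain has the
most atomic contacts with it; remaining chains group to the nearest copy;
of those, the two nearest the peptide are the TCR pair (validated by their
disulfides) and the farthest is β2m; TCRα is the TCR chain whose
variable-domain disulfide centroid lies nearer the peptide N-terminus
(canonical diagonal docking places Vα over the peptide's N-terminal half).

## Docking geometry

Crossing-angle conventions differ across the literature, so the convention
here is explicit and configurable: the TCR axis is the vector connecting
the Vα and Vβ variable-domain disulfides (SG midpoints by default; CA
midpoints as an option), the peptide axis runs N-terminal Cα → C-terminal
Cα, both are projected into the MHC groove plane, and the angle between
the projections is reported in [0°, 180°) viewed along the peptide.  The
groove plane is the least-squares plane through the Cα atoms of the α1/α2
helix windows of the heavy chain (defaults: author residues 50–85 and
138–175, configurable), with the normal oriented toward the TCR.  The
incident angle is |90° − angle(TCR axis, plane normal)| — the tilt of the
TCR over the platform, in [0°, 90°].

Because ideal α-helices keep their Cα atoms on a ~2.3 Å-radius cylinder,
the raw-Cα plane fit has an RMS residual of ~1.6 Å on the synthetic
platform; the fitted *normal* is nevertheless stable (the helical wobble
averages out), which is what the angles depend on — toy-complex recovery
is within 0.25° across 15–120° constructions.

## Solvent accessibility and interfaces

SASA is Shrake–Rupley with a deterministic golden-spiral lattice (default
960 points, probe 1.4 Å): per-atom area is the exposed-point fraction times
the expanded-sphere area.  There is no randomness; doubling the point count
changes toy totals by <1%.  The trade-off is that the lattice is fixed in
space, so SASA is exactly translation-invariant but only
rotation-invariant to lattice resolution (≲2% at 960 points).  Radii come
from a bundled Chothia-style element/name table (versioned TSV); published
buried-surface values depend on the radius set, which is why cross-study
comparisons should allow a few percent.

BSA uses the additive convention SASA(A) + SASA(B) − SASA(AB); peptide
burial compares the free peptide with the peptide in the MHC groove (TCR
absent).  Contacts are detected on heavy atoms: any cross-boundary pair
within 4.0 Å (vdW, one record per residue pair at the closest atoms),
donor–acceptor N/O pairs within 3.5 Å with an antecedent–donor–acceptor
angle ≥120° (H-bond; capability tables per residue type stand in for the
missing hydrogens), and charged-group atoms (Lys NZ, Arg NE/NH*, His
ND1/NE2 vs Asp OD*, Glu OE*, C-terminal carboxylate) within 4.0 Å (salt
bridge).  "Within 8 Å of the peptide" for design-position selection is the
minimum heavy-atom distance to the peptide chain by default; a whole-pMHC
reference is available as a flag because the two readings genuinely differ
in practice and both are in common use.

## The binding score

The pose score is a deliberately simple, fully documented physics-style
analogue of the scoring functions used for fixed-backbone design — it is
**not** a reimplementation of any published force field, and its absolute
values are not comparable to one.  The design protocol only needs a
*ranking* of candidate substitutions, which is what the score provides.

Terms, per unique heavy-atom pair (intra-residue pairs, 1-2/1-3 pairs
across the peptide bond, and 1-2/1-3 pairs across disulfide bridges
excluded; everything smoothly switched to zero over 5.5–6.0 Å):

* split Lennard-Jones with rmin_ij = rh_i + rh_j, ε_ij = √(ε_i ε_j):
  for r ≥ rmin the attractive branch ε[(rmin/r)¹² − 2(rmin/r)⁶]; for
  r < rmin the attraction saturates at −ε and the remainder goes to the
  repulsive term, linearly extrapolated below 0.6·rmin so clashes stay
  finite with a continuous first derivative;
* screened Coulomb 332.064·q_i q_j/(ε₀ r²) with the distance-dependent
  dielectric ε(r) = ε₀·r, ε₀ = 10 — standard practice for implicit-solvent
  repacking; charges are a reduced set (formal charges on Lys/Arg/Asp/Glu
  side chains, His neutral, small backbone dipole, C-terminal charge only
  when OXT is present) because full force-field charges are unwarranted
  without hydrogens;
* Gaussian-exclusion solvation (Lazaridis–Karplus form) with per-element
  ΔG_free, λ = 3.5 Å and atomic volumes; the composition-constant
  reference term is dropped — it cancels exactly in the binding
  subtraction;
* a short-range H-bond well (−1 kcal/mol, smoothstep 2.8→3.5 Å) on
  donor/acceptor heavy-atom pairs.

Default weights {attr 1.0, rep 0.55, coulomb 1.0, solvation 1.0, hbond
1.0}; the repulsive down-weighting follows common fixed-backbone-repacking
practice.  All parameters ship as versioned TSV tables.

The binding score is B = E(complex) − E(TCR) − E(pMHC) with the separated
partners kept at their complex coordinates — no repacking or relaxation
after separation, the literal reading of the subtraction protocol.
Because the score is strictly pairwise, B equals the cross-partner pair
sum exactly; the test suite asserts this to 1e-9 and checks term-by-term
continuity and rigid-motion invariance.

## Mutation scanning

Substitution enumeration covers all 20 natural amino acids except
cysteine *including* the wild-type identity — 19 per position, so 52
positions give the canonical 988-candidate scan.  Side chains build from
biotite's idealized residue templates: the template backbone triad is
superposed on the target N/CA/C, then the χ dihedrals are driven to the
requested rotamer.  Rotamers come from a deterministic staggered grid
(−60/60/180 per sp³ χ; −90/0/90 for terminal sp²-like χ; optional ±30°
half-steps as an "extra rotamers" switch) rather than a statistical
library — self-contained, exactly reproducible, and adequate for ranking;
the library interface accepts a richer set.  Proline keeps its template
ring; glycine ends the search (no side chain).

Only the mutant side chain repacks (a neighbor-shell option exists, off by
default); the backbone and every other residue are bit-identical before
and after placement, which the tests assert literally.  The rotamer search
minimizes the total pose energy via an incremental side-chain-vs-
environment evaluation; ties break to the lowest rotamer index.  Scans are
pure functions of their inputs: identical configuration and seed give
byte-identical TSV output, and each result embeds a config fingerprint.
Failed candidates are recorded with an error flag, never dropped.

Double mutants place the two side chains independently when they cannot
interact; if any pair of placed side-chain atoms falls within the energy
cutoff, an exhaustive rotamer-pair search runs instead (deterministically
coarsened above 4096 combinations).  For non-interacting positions the
pair ΔB equals the sum of the single ΔBs to 1e-6 — the additivity test.

Loop refinement perturbs the φ/ψ of one random loop residue per cycle
(uniform ±10° by default), rebuilds the loop forward from the fixed
N-anchor, closes the break onto the fixed C-anchor triad by CCD (closure
RMSD < 0.1 Å over the anchor N/CA/C; unclosable proposals are counted and
rejected), and applies Metropolis acceptance at kT = 1.0 on the total pose
energy, returning the best conformation seen.  CCD is run to 500 sweeps:
its convergence is famously non-uniform (long shallow plateaus before the
final drop), and 2 Å anchor displacements on helical test loops close to
~0.02 Å within that budget.  The schedule (100 cycles, kT 1.0, 10° steps)
is recorded in the run config; it was chosen for desk-scale runtime, not
taken from any published protocol.

## SPR and ELISA

Sensorgrams follow the closed-form 1:1 Langmuir model (association
R(t) = C·ka·Rmax/(C·ka + kd)·(1 − e^{−(C·ka+kd)t}; exponential
dissociation), verified against direct ODE integration to 1e-6 RU.
Kinetic fitting is a global least squares over the whole injection series
with shared ka, kd and Rmax, optimized in log-parameter space (positivity
is structural) from three starts spanning ±2 decades around a data-derived
guess — multi-start avoids local minima without introducing any seed
dependence.  KD = kd/ka holds exactly by construction.  Standard errors
come from the Gauss–Newton covariance at the optimum.  A single-
concentration series triggers a degeneracy warning but still fits;
a fitted KD above the highest injected concentration triggers a
span warning.  No mass-transport or bulk-shift terms are modeled — the
assay being emulated is a plain 1:1 interaction.  Equilibrium analysis
fits Req = Rmax·C/(C + KD) and refuses flat response sets.

Fold change is KD_reference/KD_variant to three significant figures
(matching how mutant tables are reported: 30.8/11.3 → 2.73,
30.8/6.68 → 4.61, 30.8/1.95 → 15.8).  ELISA percent positive is exactly
100·(OD_sample − OD_neg)/(OD_pos − OD_neg), unclamped (exchange can exceed
the positive control), affine-invariant by construction, with mean ± SEM
over replicates (default n = 4).  Binder categories use configurable
thresholds, defaults strong ≥ 40% and intermediate ≥ 10%; these cutoffs are inferred
defaults for the KRAS peptide panel, not measured constants.

## Synthetic fixtures: what they emulate, and what they do not

The toy complex is a geometric idealization, not a homology model.  An MHC
platform stand-in (two antiparallel ideal α-helices, φ/ψ = −57/−47,
author-numbered to match the default groove-helix windows) flanks an
extended 9-mer peptide (VVGAVGVGK); a short helical β2m stand-in packs
under the platform; two TCR variable-domain stand-ins (helix hairpins,
each with a real engineered CYS–CYS disulfide) are rigidly placed so the
disulfide-connecting vector makes exactly the requested crossing and
incident angles (defaults 62°/8°).  Every coordinate gets a small seeded
jitter (σ = 0.03 Å), then all side chains are iterated to their
minimum-energy rotamers until a fixed point — which is why wild-type
self-substitutions later scan to ΔB = 0 exactly.  Ground truth (angles,
roles, atom counts, the 8 Å design positions measured with plain distance
arithmetic) is emitted alongside, and as a sidecar JSON on disk, so checks
never re-derive it from the fixture.

The planted-clash benchmark extends a synthetic peptide lysine toward a
TCR residue's CB, ending at 0.7× the Lennard-Jones contact distance, and
rebuilds that residue as arginine at its maximum-clash rotamer.  Any
substitution that keeps a Cβ retains the planted clash, so glycine is the
recorded clash-relieving answer (and arginine → alanine still strictly
reduces repulsion, since the extended arginine clashes worse).  The
generator verifies by scoring that the relief exceeds 1 kcal/mol before
returning the case.

What passing these fixtures shows: the geometry, interface, scoring,
scanning and fitting machinery is internally consistent, deterministic,
and recovers planted ground truth.  What it does not show: agreement with
any particular deposited structure's numbers (crossing angles, buried
areas, NCS RMSDs), which depend on real coordinates, radius sets and
convention details; nor that the simplified score reproduces any published
force-field energy decomposition — only the decomposition *structure*
(attractive/repulsive vdW, electrostatics, solvation) is mirrored, and
that is deliberate and out of numeric scope.  Crystallographic noise,
B-factors and alternate conformers are not emulated.

## Problem sizes

The shipped defaults keep everything desk-scale: toy complexes are ~1000
heavy atoms; a full planted-clash scan (≈250 candidates) takes ~15 s; the
simulate-and-refit benchmark (two injection series × 20 seeds) runs in a
few seconds.  These sizes were chosen as the package's own test scale —
they exercise every code path while keeping the suite quick to run.
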