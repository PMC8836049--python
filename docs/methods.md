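# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Structures, trajectories and regions

A structure is an ordered atom list plus one or more coordinate models in Å;
a trajectory is a single-model topology plus strictly increasing frame times
in ns, with frame 0 defining the reference state for every time-zero
normalised quantity. Multi-model PDB files are read as trajectories with
uniform spacing (default 0.25 ns/frame) unless a sidecar text file supplies
explicit times.

Residues carry two indices: a 1-based sequential internal index used by all
matrix-valued outputs, and the author residue number from the file, used by
region definitions — published region bounds (G61–A64 and the like) are
author numbers. Insertion codes are rejected outright and only the first
alternate location of an atom is kept; the intended inputs (NMR-derived
conformers and simulation snapshots) use neither. "Backbone" and "mainchain"
are the same four-atom set {N, CA, C, O}. The packaged default region map
covers the 173-residue mature γD-crystallin chain; the N-td/C-td split is
taken as residues 1–82 / 88–173 with the linker left unassigned, so
domain-restricted analyses never double-count linker contacts.

## Contacts and the fraction Q

A residue pair is in contact when any heavy-atom pair sits within the
cutoff, default 6.5 Å, with a *closed* boundary (literal "within"). The
default minimum sequence separation is |i−j| ≥ 1, i.e. no pairs are
excluded; sequence-adjacent contacts are therefore part of the denominator,
which makes per-region Q floors non-zero even after complete detachment — a
flag raises the separation (e.g. to 3) for tertiary-contact-focused maps.
Detection runs through a k-d tree; the all-pairs double loop is kept in the
package as the definitional oracle and the two are required to agree
set-exactly.

Q(t) divides the number of contacts present at time t by the number at
frame 0. The numerator deliberately counts *all* contacts, native or not, so
Q can exceed 1 when compaction creates new pairs; `strict_native=True`
intersects the numerator with the reference set instead. Region-restricted
Q keeps every pair with at least one member inside the region ("contacts of
the region with its neighbours"). The subtractive map between two ensembles
is computed two ways, because published subtractive analyses are ambiguous
about the reference: `raw` subtracts ensemble frequencies directly, `loss`
first subtracts each trajectory's own frame-0 indicator so that ensembles
started from different structures are each measured as change-from-self.
Neither mode is asserted to be the published one; both are exact negatives
under operand swap.

## Secondary structure and unfolding events

Backbone hydrogen bonds use the Kabsch–Sander electrostatic model with
prefactor 0.42·0.20·332 = 27.888 kcal·Å/mol and the −0.5 kcal/mol call
threshold; energies are clamped at −9.9 kcal/mol as in reference
implementations. Amide hydrogens are rebuilt 1.0 Å from N anti-parallel to
the preceding C=O (the classic convention), so hydrogen-free files work;
prolines never donate; donors and acceptors must be ≥ 2 residues apart.
Chain breaks (CA–CA > 4.5 Å or incomplete mainchain) terminate turn/helix
pattern continuity. The label set is {H, G, I, E, B, T, C} with priority
H > E > G > I > B > T > C; solvent accessibility, bend and chirality flags
of full DSSP are out of scope. On ideal-geometry fixtures the assignment is
cross-checked in the test suite against mdtraj's DSSP implementation and
must agree on ≥ 90% of interior residues.

Unfolding events are per-region: β-content (fraction of E/B labels) is
smoothed with a 5-frame centred rolling window to suppress single-frame
flicker, and an event fires at the first time the smoothed value drops below
the threshold (default 50%) and stays below for ≥ 5 sampled frames. Regions
that start below threshold never produce an event. A region ending below
10% β with another event region within 10 residues is classed `melt` rather
than `beta_loss`. Threshold, persistence and window are tunable; the
defaults were fixed once against the scripted generator, and the acceptance
surface is onset localisation to ±2 sampled frames and exact ordering for
onsets ≥ 5 frames apart.

## Aromatics

Ring centroids are unweighted means over the standard ring atom sets
(6 atoms for Phe/Tyr, 9 for Trp, 5 for His; His is only optionally aromatic
and off by default). An interaction is present when the centroid distance
lies in the closed 4.5–7.0 Å band; persistence is the percentage of sampled
frames in band. A nearest-ring-atom metric is available for
minimal-distance-style traces, since published distance plots do not state
which metric they use; the centroid metric is the default because it is the
band criterion's native metric. Clusters are connected components (≥ 3
members) of the presence graph — membership is deliberately transitive — and
a formation event requires a member set absent at the reference frame to
persist as a component for ≥ 5 consecutive sampled frames.

## Kinematics

Superposition is the proper (det = +1) Kabsch solution via
`scipy.spatial.transform.Rotation.align_vectors`; collinear selections are
rejected. RMSF uses a two-pass reference: align to frame 0, average, realign
to the average, then measure fluctuations — the per-residue value is the
mean over the residue's mainchain atoms. Under isotropic Gaussian noise of
width σ the expected per-atom RMSF is σ√3, which the calibration test
checks to 5% at 2000 frames; note the rigid fit absorbs an O(1/N) share of
any single atom's motion, which matters for few-atom toys but not for
protein-sized selections.

Essential-dynamics PCA aligns every frame to frame 0 on the selection
(default mainchain) before accumulating covariance — alignment removes the
six rigid-body modes, which is standard practice though rarely stated.
Eigenpairs are sorted by descending eigenvalue; each eigenvector's sign is
fixed by making its first component of magnitude > 1e-12 positive, so
repeated runs are bit-comparable. The spectrum must be non-negative within
tolerance and sum to the covariance trace within 1e-6 relative.

Interdomain motion uses a simplified closure/twist decomposition rather
than a full dynamic-domain search: after superposing on the fixed domain's
mainchain, the moving domain's Kabsch rotation gives axis **n** and angle;
with **d** the reference unit vector between domain mainchain centroids,
%twist = 100·(n·d)² and %closure is the complement, so the two always sum
to exactly 100. A frame is labelled closure iff %closure ≥ 50. The hinge
point — needed only for visualisation — is the projection of the moving
domain's reference centroid onto the screw axis, obtained by least-squares
solution of (I − R)p = t⊥. Frames rotating less than an angle floor of 1.0°
carry no meaningful axis and are excluded from motion-time fractions (their
count is reported; an all-excluded trajectory yields NaN fractions with a
warning). Domains here are user-specified regions; when part of a domain
detaches during the trajectory, the superposition anchor should be a region
that remains rigid (the presets expose `domain1_core` for exactly this).

## Energetics

The breakdown mirrors the classical partition E_pot = E_valence + E_nonbond,
E_valence = E_str + E_bend + E_tor + E_inv, E_nonbond = E_van + E_elec +
E_hbond, enforced as exact sum identities on every scorer output; terms a
scorer does not implement are recorded as zero and flagged. The built-in toy
scorer implements harmonic bond stretch with the *declared* convention
E_str = k·(r−r0)² (not ½k — the convention is part of the parameter object's
contract), Lorentz–Berthelot-combined 12-6 Lennard–Jones, and Coulomb with
a uniform dielectric and constant 332.0637 kcal·Å/(mol·e²). No cutoffs, no
force evaluation, no full force-field parameterization: the module's purpose
is exact ΔE bookkeeping between designated frames with injectable scorers,
and ΔE telescopes exactly across intermediate frames. ΔE uses single frames
at the two endpoints by default; window averaging is a caller-side choice.

## The synthetic-data generator

The generator produces an idealized two-domain antiparallel β-sandwich:
strands are built by internal-coordinate (NeRF) construction at β dihedrals
(φ = −139°, ψ = 135°, ω = 180°) with standard bond lengths and angles, and
each added strand is placed rigidly by least-squares against the canonical
antiparallel ladder targets (narrow-pair N···O = 2.9 Å both directions,
paired CA–CA ≈ 5 Å), so the sheets genuinely satisfy Kabsch–Sander bridge
patterns rather than merely looking strand-like. Designated residues carry
idealized planar rings for the aromatic analyses. The second domain is the
same sheet translated along the strand axis with an 8 Å gap — enough for a
small interface contact set and rigid-body motion tests.

A script turns the structure into a trajectory deterministically from its
seed: rigid interdomain rotations ramp linearly over the whole trajectory
with an axis built from the scripted twist fraction (axis = √f·d + √(1−f)·p,
p ⊥ d); strand detachments displace a region linearly over a ramp (onset =
first ramp frame); cluster events translate member side chains onto a
regular simplex with the target edge length (supports 2–4 members, the
maximum for equal pairwise distances in 3-D); isotropic Gaussian noise of
stated σ is added last, to every frame including frame 0. Scripting a
rotation and a detachment onto the same atoms is an error, since the ground
truth would be ill-defined. Default preset conditions: 100 frames at
0.25 ns/frame, noise σ = 0.15 Å, detachment displacements of 15–20 Å with a
5-frame ramp — chosen once as a desk-scale emulation in which events are
unambiguous yet noise is non-trivial.

What the generator does **not** emulate: solvent and denaturant chemistry,
force-field dynamics, thermal unfolding kinetics, side chains beyond the
aromatic rings, or the real γD-crystallin geometry (Greek-key strand
lengths, domain interface packing). Passing tests therefore demonstrate
*parameter recovery* — that each analysis recovers the quantities a script
planted, at stated tolerances — not that the pipeline's defaults are tuned
for any particular force field's output. The published-vocabulary region
names in the presets are aliases onto toy strands chosen so that no scripted
strand is a sheet neighbour of another scripted strand, making each region's
contact and β-structure loss attributable to its own scripted event.

The composition stand-in (`build_composition_stand_in`) is a synthetic
CA-only chain reproducing the documented residue makeup of the mature
γD-crystallin chain (173 residues; 14 Tyr, 4 Trp, 6 Phe) with deterministic
filler elsewhere; it exercises the parse→composition path offline and is not
a deposited structure.

Ion arithmetic: ions per species = round(c·N_A·V) with c in mol/L and V the
cubic box volume in litres; 136.7 mM in a 7.0 nm box gives 28, matching the
published solvation setup.

## Problem sizes and determinism

Test and acceptance workloads use 48–72-residue toys, 100-frame scripts,
2000 frames for the RMSF calibration and 60–200 random 300-residue frames
for the contact-oracle equivalence — sizes at which every stage runs in
seconds while the statistics under test (onset localisation, RMSF
convergence, spectral identities) are already stable. All randomness flows
from explicit seeds; the pipeline writes a manifest of sha256 checksums and
identical config + inputs reproduce identical bytes.

## Known limitations

- The closure/twist split is axis-geometric only; it does not identify
  dynamic domains, place hinge residues, or reproduce any specific published
  decomposition tool's output.
- The DSSP-style assignment omits accessibility, bend, chirality and
  polyproline classes, and assigns π-helix only via the 5-turn pattern.
- Q with min_separation=1 includes sequence-neighbour contacts, so region Q
  never reaches 0 after detachment; interpret region Q drops relative to
  their own baseline.
- The toy energy scorer is for bookkeeping contracts, not energetics of real
  proteins; published ΔE magnitudes are not reproducible without the
  original force-field parameterization and starting structures.
- Multi-chain files are supported by the reader, but region definitions are
  author-number ranges without chain qualifiers.
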