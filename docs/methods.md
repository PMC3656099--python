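# Methods

## Scope and model

`strandmig` analyses trajectories of an RNA construct in which two helices
compete for one switching strand.  The default construct registry
(`6P1_11AT`) encodes:

* a P1 5′ strand (hybrid residues 1–6: G1 U2 U3 A4 U5 G6),
* a switching strand (101–113),
* an AT 3′ strand (135–145),
* named aptamer-core residues carrying a dual numbering (aptamer id =
  hybrid id + 2).

P1 ordinal *p* pairs 5′-residue *p* with switching residue 114 − *p*
(ordinal 1 ligand-proximal, ordinal 6 the closing pair at the P1/AT
boundary); AT ordinal *a* pairs switching residue 112 − *a* with 3′-residue
134 + *a* (ordinal 1 at the boundary, outward).  Ordinals 1–2 of P1 and 5–11
of AT are fixed; the four shared positions (switching residues 108–111) are
the competition region.  The canonical start state pairs three of them in
the AT helix and leaves the boundary residue U110 unpaired between its two
potential partners A4 and A136; the canonical end state is the full
six-pair P1 helix.  `diff_pairing` between those two maps therefore reports
exactly three AT→P1 conversions plus one unpaired→paired event.

## Hydrogen-bond statistics

Every Watson–Crick position carries the standard donor/H/acceptor triples
(2 for A-U type pairs, 3 for G-C type).  Two monitors act on the measured
geometry (d = H···acceptor distance, θ = donor–H–acceptor angle):

* **binary presence**: d < 3.5 Å and θ > 145° (cutoffs configurable);
* **continuous probability**:
  `HBP = clip(exp(−(d + λ(cos θ − cos θ_ref) − d_ref)/λ), 0, 1)`.

The continuous form equals 1 at the reference state, decays exponentially
with decay length λ as the distance stretches beyond `d_ref` or the angle
bends away from `θ_ref`, and is clamped because the raw exponential exceeds
1 for compressed geometries while the quantity is used as a coordinate on
[0, 1] axes.  Defaults: `d_ref = 2.1 Å`, `θ_ref = π`, `λ = 0.5 Å`.  The
reference distance was chosen at the loose end of the ideal-template bond
geometries (1.86–2.01 Å H···acceptor) so that an ideally formed bond scores
exactly 1; λ = 0.5 Å makes the statistic fall to ≈0.06 at the binary
distance cutoff, keeping the two monitors consistent.  All three values are
configuration (`HBPParams`), never hard-coded in operations.  Helix-level
fractions are per-frame arithmetic means over the helix's full master bond
list; no time smoothing is applied by default.

## Reduced landscape and event detection

The per-frame pair (f_P1, f_AT) of averaged bond statistics spans the
reduced conformational space; populations are binned on a 50×50 grid over
[0, 1]² and displayed as log(count) with empty bins masked.  A migration
event is the first frame at which **all six** P1 positions satisfy the
per-position criterion — by default all their binary bonds, alternatively a
nucleobase RMSD below 1.5 Å against the bundled ideal pair template.  The
criterion is monotone: loosening cutoffs can only move the event earlier.
The event's run is the maximal contiguous block of qualifying frames; its
lifetime uses the end-minus-start convention at the recording interval
(0-based frames, 200 ps/frame by default), so a run spanning frames
6544–6635 lasts 91 × 0.2 = 18.2 ns.

## Synthetic generator

The generator is the package's validation instrument: it renders a scripted
pairing schedule into coordinates so that every analyzer can be compared
frame-by-frame with known ground truth.

* **Templates.**  Nucleobases use standard-reference-frame heavy-atom
  coordinates with WC-donor hydrogens placed collinearly toward the
  idealized partner acceptor; one canonical C1′ position is shared by all
  bases so helically placed strands have exactly constant C1′–C1′ step
  distances.  The backbone is a simplified six-atom arc (P, O5′, C5′, C4′,
  C3′, O3′) that closes the chain (~1.5 Å O3′–P gap) under the default
  A-form parameters; it supports RMSD/pseudo-dihedral/clash monitors but is
  not chemically accurate sugar-phosphate geometry.
* **Helix construction.**  Ideal A-form placement with twist 32.7°/step and
  rise 2.81 Å/step (standard fiber values, configurable).  The two helices
  share one coaxial axis: P1 ordinal *p* at helical step 7 − *p*, AT ordinal
  *a* at step 1 − *a*; the switching strand ascends the axis continuously in
  both helices.
* **Pairing states.**  A residue whose position is paired elsewhere, or
  unpaired, has its base swung 90° out of the pair plane about the
  tangential axis through C1′ (the boundary residue additionally sits midway
  between its two helical homes).  This documented flip path — not a
  physical trajectory — breaks both the distance and angle criterion of all
  scheduled bonds of that position.
* **Noise.**  Seeded isotropic Gaussian displacement, by default rigid per
  residue per frame.  Rigid jitter emulates thermal libration while
  preserving covalent geometry; independent per-atom jitter (available as
  `noise_mode="atom"`) distorts the donor–H–acceptor angle through the ~1 Å
  lever arm at the hydrogen and is therefore unsuitable for exercising the
  angle-based detector at realistic amplitudes.
* **Markers.**  A pseudo-ligand sulfur and a core Mg²⁺ site are placed from
  per-frame distance scripts: the Mg²⁺ sits at a fixed pocket position,
  singly-constrained electronegative atoms (A8 P, G9 O6, and the three J3/4
  phosphates) along fixed directions at the scripted distance (exact at
  σ = 0), doubly-constrained atoms by sphere intersection with a
  triangle-inequality feasibility check.  Default scripts keep the J3/4
  contacts short in both conditions and let the J1/2 contacts drift from
  ~2.2 Å to 6 Å when the ligand is absent.  The sulfur–carbonyl readout
  (U5 O2) is positioned to sit ~3.2 Å once P1 pair 5 forms; it is measured,
  not scripted, because those atoms move with the pairing state.

### Bundled scenario

The desk-scale study conditions are 1,000 frames at 200 ps/frame with the
event at frame 400 and default noise σ = 0.1 Å.  After the event the
closing pair (ordinal 6) frays once the full helix has lived 92 frames
(lifetime 91 × 0.2 = 18.2 ns), and pair 5 is disrupted over a window sized
so its post-event occupancy is ≈ 0.247 — the observed fraction of post-event
snapshots displaying that pair — at the scaled trajectory length.

### What the generator does and does not emulate

It reproduces the *observables* the analysis stack consumes: scheduled bond
geometries, competing-helix occupancy, marker contacts, fraying windows.  It
does not produce physical dynamics: no force field, no solvent or ions
beyond the single scripted Mg²⁺ marker, no chain continuity across the
P1/AT boundary while the competing region is split between helices, no
tertiary motifs (kink-turn, pseudoknot).  Passing tests therefore
demonstrate that the analyzers recover known ground truth exactly and
degrade gracefully under noise — not that they have been validated against
experimental trajectories.

## Structure metrics

* **Superposition** is closed-form least-squares (SVD with a proper-rotation
  determinant correction); tests cross-check it against a brute-force
  quaternion-grid search with local refinement to 10⁻³ Å.
* **Base-pair RMSD** superposes the two nucleobases' heavy atoms onto the
  bundled ideal pair template (the same ideal geometry serves both
  helices).  **Backbone RMSD** uses P, O5′, C5′, C4′, C3′, O3′, excluding
  atoms absent from either structure (e.g. a missing 5′ phosphate).
* **Pseudo-dihedrals** follow the standard signed torsion (cis 0°, trans
  180°, invariant under order reversal), matching MDAnalysis/mdtraj to
  float32 precision; the default quartet spanning a dinucleotide step is
  (C4′ᵢ, Pᵢ₊₁, C4′ᵢ₊₁, Pᵢ₊₂), configurable.
* **Energies** are monitoring proxies: a minimal per-element 12-6 LJ table
  (C/N/O/P, Lorentz–Berthelot, 10 Å cutoff, hydrogens excluded) and a
  screened Coulomb term `k_e q_i q_j exp(−κr)/r` with κ = 0.19 Å⁻¹ and, by
  default, a −1 charge on each phosphate P.  Only relative values and ranks
  are meaningful; no solvation model or minimization is implied.
* **Clash counting** is strict `<` on heavy-atom pairs with 1-2/1-3
  exclusions derived from the simplified connectivity (including the C4′–C1′
  pseudo-bond that stands in for the omitted sugar ring).

## Clustering and model selection

State clustering uses seeded multi-start k-means (n_init = 10, squared
Euclidean, k = 5 by default) on per-pair nucleobase RMSD features; each
state's representative is the frame nearest its centroid (lowest index on
ties).  Candidate intermediate models pass three hard filters — zero
clashes, an open ligand pocket (no foreign heavy atom strictly inside a
4 Å radius of the pocket centroid; a geometric proxy, since accessibility
has no unique operational definition), and membership of the favorable
boundary-stacking class (k = 4 k-means on the two hinge vdW energies;
favorable = lowest mean energy sum) — and are then ranked by ascending
LJ + screened-Coulomb score.

## Numerical conventions and degenerate inputs

Frames are 0-based; spans are end − start (exclusive-of-start counting).
Histograms place boundary values in the last bin so counts are always
conserved.  k-means requires at least k distinct feature vectors and fails
loudly otherwise (the pipeline records the skip instead of aborting).
Superposition requires ≥ 3 non-degenerate points; dihedrals reject collinear
inner triples; marker scripts reject non-positive distances and infeasible
two-center constraints.  All stochastic operations take explicit integer
seeds, recorded in the pipeline report; identical configuration and seeds
reproduce CSV/JSON outputs byte for byte.

## Problem sizes

The package's own validation runs use 120–200-frame schedules for unit and
property tests, 50 seeded replicates at σ = 0.3 Å for detection robustness,
and the 1,000-frame bundled scenario for the end-to-end pipeline; these
sizes were chosen so the whole suite exercises every stage in seconds while
leaving the statistics (recovery rates, occupancy fractions) stable.
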