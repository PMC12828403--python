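# Methods

`ddpks` is a pipeline for comparative structural analysis of a family of
dimeric iterative type I polyketide synthases (PKSs), built around the 40
highly related PKSs of *Dictyostelium discoideum* and their prototype,
Pks16, the organism's presumed fatty acid synthase. It covers five
analyses: merging fragment-wise homodimer predictions into full-length
models, characterizing domain–domain interfaces in a family-wide reference
numbering, identifying consensus acyl carrier protein (ACP) docking sites
across prediction ensembles, summarizing the reaction chamber an ACP
traverses, and disambiguating near-identical paralogs (Pks16 vs Pks17) at
the peptide level. Each analysis is exercised end to end on synthetic
fixtures with planted ground truth.

## Reference numbering

All cross-paralog statements are made in Pks16 coordinates. A reference
map is a strictly monotone partial bijection between Pks16 positions and a
paralog's native positions, derived from one optimal global pairwise
alignment (affine gaps: the first gap residue costs the open penalty, each
additional residue the extension penalty; end gaps are penalized).
Parameters are the community defaults BLOSUM62 / open 11 / extend 1; the
traceback is deterministic (first alignment in the aligner's fixed
enumeration order). Positions paired with a gap in either row are simply
absent from the map and surface downstream as explicit `MISSING` values,
never as silent drops.

Percent identity is `100 × matches / aligned columns`, gap columns
included. For near-full-length homologs such as Pks16/Pks17 the
denominator choice is insensitive; it is fixed here so that identity
figures are well defined. Maps built from alignments under 15% identity
are flagged unreliable but still usable.

The domain registry (`data/domains_pks16.cfg`) holds curated reference
ranges for KS, flanking, AT, DH, MT, KR_s, ER, KR_c and ACP. Only a few
boundaries are anchored by well-established landmarks (the KS/ACP
interface mutation sites 86–88, the MT span and lid, the
phosphopantetheinylated ACP serine at 2543); the remainder are editable
curated defaults, and tests assert only the anchors.

## Fragment merging

A ~5,200-residue homodimer exceeds what one structure prediction job can
cover, so each synthase is predicted as two overlapping dimeric fragments
sharing the KS dimer: KS+AT+DH, and an AT-less construct carrying
KS*+DH+MT+KR_s+ER+KR_c+ACP (KS* carries aspartates at reference 86–88 to
abrogate the otherwise dominant KS/ACP association; the `refmap` mutation
utility reproduces this construct from a reference-numbered spec).

Merging superposes the second fragment onto the first through the shared
KS dimer using CA atoms over the full KS reference span present in both —
CA-only fitting is robust to side-chain divergence between independent
predictions. Both chain pairings (A→A/B→B and A→B/B→A) are fitted and the
lower-RMSD pairing kept; fits with fewer than 20 paired CA atoms are
rejected as unreliable. Each output chain then takes residues up to and
including the junction (reference 935, just downstream of the conserved
KS–DH linker proline) from the first fragment and everything downstream
from the transformed second fragment, preserving native numbering.

The seam is reported, never repaired: the junction report gives the
CA(junction)–CA(junction+1) distance and the count of inter-fragment
heavy-atom pairs under 2.0 Å per chain. No minimization, loop rebuilding
or density-guided refinement is attempted.

The superposition primitive is the standard SVD (Kabsch) solution with the
determinant sign correction that suppresses reflections. Tests check it
against a planted-rotation oracle, a Monte-Carlo noise expectation
(residual RMSD ≈ σ·√(3·(1−3/N)) for N points, 6 degrees of freedom
absorbed), and a 10° Euler-grid search it must never lose to.

## Interfaces

A contact is a residue pair with any heavy-atom pair within 4.5 Å (the
literature gives no operational definition of "contact"; the cutoff is
overridable and echoed in every report). Hydrogen bonds are N/O
donor–acceptor pairs within 3.5 Å; when explicit hydrogens are present a
D–H…A angle of at least 120° is additionally required. Salt bridges
(charged-group atoms within 4.0 Å) are flagged on the contact rather than
reported separately. Pocket insertion — e.g. the conserved proline at
reference 935 inserting into the KS pocket at 53/55/56/59 — is
operationalized as: at least 60% of the inserted side chain's heavy atoms
within 5.0 Å of pocket atoms, and at least 3 distinct pocket residues
contacted at 4.5 Å. These thresholds are recorded in each
`PocketInsertion` result.

An interface fingerprint re-expresses contacts as a set of
reference-position pairs via the two reference maps (unmapped contacts are
dropped with a count), which makes fingerprints invariant to native
numbering shifts and to rigid motion of the model; similarity between
fingerprints is the Jaccard index.

## Consensus ACP docking sites and the reaction chamber

Each prediction in an ensemble is placed in a canonical enzyme frame by
superposing its enzyme-domain CAs onto the Pks16 prototype (per-enzyme
frame conventions: the KS dimer for KS/ACP, the AT of chain B for AT/ACP,
the large MT subdomain of chain A for MT/ACP, the KR_s, DH or ER of chain
A for the respective partners; the frame-chain restriction is an explicit
argument). A pose is the set of CA positions of the mapped ACP core
(reference 2524–2575, at least 10 required) in that frame, plus the CA of
the phosphopantetheinylated serine (2543). Framing RMSD above 5 Å flags
the pose unreliable. When a model carries several ACP copies, each copy
yields a pose and the copy with the most enzyme–ACP heavy-atom contacts is
listed first (it is the one actually docked).

The pose metric is the RMSD over shared ACP-core CAs in the common frame
with **no** re-superposition, so it couples translation and orientation in
one number and directly expresses "same docking site". Poses are clustered
by average-linkage agglomerative clustering cut at τ = 8 Å; input order
cannot matter because poses are canonicalized by source id before
clustering and ties break lexicographically. The consensus site is the
largest cluster (ties toward the smaller mean pairwise distance), and a
synthase "carries" the site iff at least one of its poses is a member —
synthases are counted, not poses. Because no quantitative consensus
criterion is established in the literature, the CLI exposes τ and a
sensitivity grid τ ∈ {4, 6, 8, 10, 12} Å is defined for reporting.

The reaction chamber is summarized by overlaying the per-enzyme consensus
serine anchors in one common dimer frame: convex hull volume of the
anchors (0 with a flag below 4 points or for degenerate geometry) and the
maximum pairwise displacement. A C2 dimer has exactly two equivalent
chambers; with explicit chamber centers anchors are assigned by proximity,
otherwise the single chamber listing is mirrored and flagged as the
C2-equivalent copy.

## Peptide-level paralog disambiguation

In-silico tryptic digestion cleaves C-terminal to K or R except before P,
with up to two missed cleavages by default (the standard search-engine
setting). Detected peptides are matched to each paralog by exact substring
occurrence (overlaps counted); verdicts are unique-to-A / unique-to-B /
shared / unmatched, with duplicates collapsed and multiplicities kept.
Matching treats I and L as distinct by default — classification operates
on sequence-level matches — with an I/L-collapsed mode available since
mass spectrometry cannot distinguish the two. Search-engine modification
annotations (bracketed tokens, flanking-residue dot notation) are stripped
before matching. Protein-table filtering is a plain threshold filter on
unique-peptide and PSM counts over already-scored rows; FDR estimation
itself is the search engine's job and out of scope.

## Synthetic data: what it emulates, and what it does not

The generators produce exactly the structures the analyses consume, with
the planted truth stored alongside:

- **Dimers** — idealized α-helical CA traces (rise 1.5 Å, radius 2.3 Å)
  with minimal backbone atoms (N, C, O, CB), one helix bundle per domain,
  chain B an exact C2 image of chain A. These are shapes for geometry
  tests, not chemistry: no realistic side chains, secondary-structure
  diversity, or inter-domain packing.
- **Fragment pairs** — a parent dimer cut into the two overlapping
  constructs, the second moved by a known rigid transform, both perturbed
  by iid Gaussian coordinate noise (default σ = 0.3 Å per coordinate, a
  plausible scale for coordinate differences between independent
  predictions of the same fold). Recovery is scored against the parent.
- **Pose ensembles** — 40 synthetic paralogs, 27 of which carry a planted
  consensus site, 5 poses each, consensus poses jittered at σ = 2 Å per
  coordinate and outliers displaced at least 30 Å; every model also gets a
  random global rigid move so pose extraction must genuinely re-frame it.
  These defaults mirror the family-scale study design (a 40-member family
  with a majority sharing the ER/ACP site, five predictions per job).
- **Paralog pairs** — sequences built as concatenations of tryptic blocks
  (K/R terminators, K/R/P-free interiors), the second derived from the
  first by point substitutions: one inside each planted unique peptide,
  plus filler substitutions in undetected blocks until the target identity
  (default 96%) is met. Defaults mirror the Pks16/Pks17 design: 87
  detected peptides splitting 29 unique-to-A / 0 unique-to-B / 58 shared.
  The construction guarantees every planted peptide is a genuine 0-missed
  tryptic product and that unique peptides overlap a substitution.

Passing tests on these fixtures demonstrates the pipeline's correctness —
that each stage recovers what was planted — not that real prediction
ensembles satisfy the generators' assumptions (isotropic noise, rigid
domains, unambiguous consensus separation). Analyses of real deposited
prediction sets should treat the τ sensitivity report and the seam metrics
as first-class outputs, not formalities.

## Numerical choices and degenerate inputs

- Rotations must be orthonormal within 1e-8 with determinant +1;
  reflections are rejected at construction.
- Collinear point sets in superposition warn and return the best proper
  rotation rather than failing.
- Alternate locations keep the highest-occupancy conformer (ties to the
  first altloc alphabetically); hetero records are parsed but excluded
  from geometry unless explicitly selected.
- Models exceeding PDB fixed-width columns (residue number > 9999,
  multi-character chain ids, > 99999 atoms) are written as mmCIF with a
  warning; round trips are exact to format precision (0.001 Å for PDB).
- Cluster and consensus ties break deterministically (size, then mean
  pairwise distance, then lexicographic source id).
- Convex hulls of coplanar/collinear anchors report volume 0 with a flag
  instead of erroring.

## Problem sizes

Test and acceptance runs use deliberately small instances chosen to
exercise every code path at full statistical strictness: 180-residue
3-domain toy dimers (20 seeds for merge recovery), 40-paralog / 200-pose
ensembles (25 seeds for consensus recovery in the test suite, 5 in the
acceptance script), ~2,600-residue paralog pairs, 100-instance contact
oracles and exhaustive alignment enumeration for sequences up to length 6.

## Known limitations

- The consensus criterion (metric, linkage, τ) is a documented
  operationalization; published membership counts for real ensembles may
  require a different τ, which the sensitivity grid makes visible.
- The merge never repairs the seam; downstream users requiring chemically
  continuous junctions must rebuild them externally.
- Hydrogen-bond detection without explicit hydrogens is purely
  distance-based and chemically permissive.
- The percent-identity figure depends on the stated alignment parameters;
  other parameter choices can shift it by a fraction of a percent.
- No buried-surface-area or energetic scoring; interfaces are described
  geometrically only.
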