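# Methods

This note documents the models, rules and numerical choices behind the
package, the design decisions taken where the design was genuinely open,
and the limits of what the synthetic benchmark can establish.

## Interface definition

Two residues from different domains are in contact when the minimum
heavy-atom distance between them is **≤ 4.5 Å** (inclusive boundary; the
cutoff is configurable). All residues participating in at least one contact
form the domain–domain interface; its size `L` counts **both sides** —
this matches the convention under which the interacting rule (`L ≥ 20`)
and the score normalization are stated. Residues lacking a Cα may still
contribute contacts (and count toward `L`) but are excluded from alignment
coordinates. Neighbor search uses a k-d tree; tests assert exact agreement
with the all-pairs double loop.

Planarity is the RMS of perpendicular distances of interfacial Cα atoms
from their total-least-squares plane (plane through the centroid, normal
along the smallest principal axis). Note this is TLS, not a z-regression:
test fixtures are built so the optimal plane is known by symmetry.

## IS-score and the alignment search

For an alignment of query interface Q (length `L_Q`) onto template T:

    S  = (1/L_Q) · max Σᵢ fᵢ / (1 + dᵢ²/d0²),   IS = (S + s0)/(1 + s0)

* `dᵢ` — Cα–Cα distance of pair *i* under the least-squares (Kabsch)
  superposition of the aligned pairs;
* `fᵢ = (cᵢ/aᵢ + cᵢ/bᵢ)/2` — contact overlap: `aᵢ`, `bᵢ` are the
  interfacial contact counts of the template and query residue at
  position *i*, `cᵢ` the query contacts of that residue preserved by the
  mapping (partner aligned, image pair a template contact);
* `s0 = 0.18 − 0.35/L_Q^0.3` (guarded: an error for interfaces so short
  that s0 ≤ 0 — the analysis only ever scores interfaces with `L ≥ 20`);
* `d0 = 0.7(L_Q−15)^⅓ − 0.1` (non-sequential) or `1.24(L_Q−15)^⅓ − 1.8`
  (sequential), floored at **0.5 Å** because both expressions are
  non-positive for `L_Q ≤ 15`.

Self-alignment gives `S = IS = 1` exactly; an empty alignment is flagged
and scores `IS = s0/(1+s0)`.

The *search* maximizes IS over (a) the two possible domain pairings
(query side a ↔ template side a, or swapped), (b) rigid superpositions and
(c) one-to-one residue assignments respecting the pairing. Seeds are the
four proper-rotation principal-axes pre-alignments plus all pairs of
contiguous interface fragments (length 6, stride 2, forward and reversed)
with compatible side labels. Each seed iterates

    Kabsch on current pairs → distance-plus-contact-overlap score matrix →
    Hungarian assignment (pairs farther than 2·d0 forbidden) → rescore

to convergence (tolerance 1e-4, ≤ 50 iterations); the global best
correspondence is rescored exactly. The procedure is deterministic for
fixed inputs; ties in the assignment resolve to the lowest query ordinal.
On small instances (5 residues per side) the heuristic equals exhaustive
enumeration over both pairings and all side-respecting bijections, each
scored under its own optimal superposition (oracle-tested, 20 instances).

The overlap term used *inside* the assignment iteration is an estimate
computed from the previous iteration's correspondence (an optimistic
constant 0.25 before any correspondence exists); the reported scores always
come from exact rescoring of the final correspondence.

## TM-score (dissimilarity filter only)

Sequential, order-preserving whole-domain comparison: a dense scan of
gapless threadings (fragment lengths L, L/2, L/4; offset stride 2) scored
directly, followed by iterative superposition + Needleman–Wunsch (gap
penalty −0.6) refinement of the best eight seeds. The score is
`(1/L_target)·Σ 1/(1+dᵢ²/d0²)` with the sequential d0. When two domains
differ in length the filter uses the **maximum** of the two normalizations
(conservative: a pair is "unrelated" only if both directions score below
0.4). Self-comparison scores exactly 1; the result is never below the best
gapless threading (tested).

## Significance

iAlign-style analyses call a match significant at p < 0.05 against a null
of random complexes. The published null parameters are not available at
desk scale, so the package calibrates its own: best-match IS-scores of
≥ 200 random (decoy-vs-decoy) interface pairs from the generator are fit
with a Gumbel (extreme-value) right tail; `p_value(score)` is the survival
function, monotone decreasing, and the p = 0.05 threshold is exposed. The
calibration is length-pooled: generated interfaces all have L ≈ 22–30, so
no length correction is attempted.

## Dataset construction rules

* **Consecutive** continuous domains: no classified domain between them.
  When the linker contains missing residues (numbering gaps merged with
  REMARK 465 annotations), its numbering-derived length must be ≤ **13**
  residues — a bound chosen so no classified domain could hide in the gap.
  Whether the cut-off also binds fully resolved linkers is an open point;
  the default applies it only when residues are missing
  (`apply_cutoff_when_resolved` switches the strict reading on).
* **Discontinuous domains** (≥ 2 segments) are represented by their major
  segment iff it is the longest segment, has ≥ **100** residues, covers
  ≥ **50%** of the domain, and contributes ≥ **20** residues to the
  interface (read as the segment's own, one-sided contribution).
* **Clustering**: greedy incremental clustering of domain sequences by
  decreasing length at **40%** identity (inclusive boundary, CD-HIT
  convention). Identity is identities / global-alignment length (match 1,
  mismatch 0, gap open −2, extend −0.5).
* **Non-redundancy**: for every cluster pair (i < j), entries present in
  both clusters with different domain numbers are candidates; one survivor
  per *domain order* — best resolution, then longest combined length, then
  lexicographic id. Reversed domain order is a distinct interface and both
  orders are kept. Equals brute-force enumeration on toy instances
  (oracle-tested).
* **Representative per protein**: best resolution first, then longest
  (the joint phrasing is ambiguous; lexicographic priority is configurable).
* **Template libraries**: a pool member survives against BOTH query
  domains (all four cross-combinations) iff no shared fold label, sequence
  identity < 25% (a surrogate for a database E-value > 1 rule, which needs
  a database context a desk-scale artifact lacks; the hook is pluggable),
  and TM-score < 0.4. The entry itself is always excluded.
* Crystal-structure quality: entries with known resolution > 2.5 Å are
  dropped; synthetic entries carry a pseudo-resolution (uniform 1.5–2.4 Å,
  plus a few 2.6+ Å entries to exercise the filter).

## Interface network

Edges point template → query when `score[q][t] ≥ threshold` (inclusive;
strict mode available). Missing matrix entries are treated as below any
threshold. The k-neighbor pair fraction is `n_k/(N·(N−1))` by depth-limited
BFS from every node; the LSCC fraction is the largest strongly connected
component of the k-step closure. Both equal dense-matrix oracles
(boolean matrix powers, mutual-reachability closure) on all tested
instances ≤ 50 nodes.

## Synthetic data: what it emulates, and what it does not

Domains are built from ideal secondary-structure geometry — helices with
1.5 Å rise and 100°/residue twist (virtual Cα–Cα bond 3.8 Å), strands with
3.3 Å rise and a ±0.94 Å zigzag — connected by circular-arc loops with
exact 3.8 Å steps, self-avoiding at 2.5 Å. Each residue carries backbone
N, Cα, C, O plus a pseudo-Cβ; these five atoms are the "heavy atoms" of the
contact rule. Domain pairs are placed rigidly by a face-biased
slide-until-contact search targeting an interface size within ±10% of the
requested value (default **26** residues, comfortably above the 20-residue
rule while achievable for 40–70-residue domains). Planted similarity copies
a source interface (both sides, all atoms) under a random rigid transform
with iid per-residue Gaussian displacement (σ = 0–4 Å) and attaches freshly
generated host cores on the outward faces, far enough (≥ 5 Å) to add no
cross-domain contacts. The default benchmark corpus holds 50 decoy entries,
20 planted entries at σ ∈ {0, 0.25, 0.5} Å, one discontinuous entry (its
major segment built wide enough to contribute ≥ 21 interface residues),
one 3-domain entry and two low-resolution entries; everything is
byte-deterministic in the top-level seed (placement sub-searches that
exhaust are retried with fresh sub-seeds drawn from the same stream).

What passing tests on this corpus establish: the printed rules and score
formulas behave exactly at their boundaries; the alignment search is
optimal on small instances and recovers planted similarity against a
realistic decoy background; the graph analysis is exact. What they do not
establish: absolute score levels, coverage statistics or connectivity
percentages on real crystal structures — real side-chain packing, sequence
redundancy structure and fold-space composition are all absent. Mean
IS-scores here (≈ 0.2 for random decoys, ≈ 1 → 0.1 as planting noise grows
0 → 4 Å) characterize the synthetic conditions only.

## Numerical choices and degenerate inputs

* Kabsch superposition via SVD with a determinant correction (always a
  proper rotation); < 3 points or collinear sets are errors.
* Hungarian assignment on the negated score matrix; forbidden pairs get a
  large finite cost and are stripped afterwards.
* Alignments need ≥ 3 pairs at every stage; seeds that collapse are
  abandoned.
* Empty interfaces are flagged, not errors; empty template libraries yield
  explicit empty search results and are reported as skipped queries.
* Sample statistics use the n−1 convention.
* Problem sizes in the default test and acceptance runs (50-decoy
  libraries, 20 planted queries, 20 replicates per noise level, ≤ 50-node
  graphs, 5-per-side oracle instances) were chosen as the smallest sets
  that make the separation and oracle claims statistically meaningful on a
  single CPU.
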