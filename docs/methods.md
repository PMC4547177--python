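# Methods

## Overview

`panmatrix` computes and curates a bacterial pan-genome from a multiple
genome alignment rather than from reciprocal-BLAST hits.  The pipeline has
four stages: (1) a blockwise whole-genome alignment (XMFA, as produced by
progressiveMauve) is concatenated into a single shared coordinate axis — the
SuperGenome — with exact bidirectional maps between every genome's own
coordinates and that axis; (2) per-genome gene annotations are lifted onto
the axis; (3) lifted genes are grouped into pan genes (ortholog groups) by
interval overlap, refined by pairwise sequence identity under a
one-gene-per-genome constraint; (4) the resulting presence–absence matrix
supports validated curation (aggregation/deaggregation with history and
undo), automatic candidate detection, and glyph-matrix rendering.

## SuperGenome coordinate system

Alignment blocks are concatenated in file order; columns are numbered
`1..total_length`.  This is a deliberate, configurable choice: an aligner
may report locally-collinear blocks in any order, and no canonical ordering
rule exists, so the file order — which progressiveMauve emits roughly along
the reference — is taken as the display order.  A super position is signed:
negative means the genome's block entry is reverse-complemented at that
column.  Coordinates are 1-based and inclusive throughout, matching both
XMFA and GFF3.

Maps are stored per block entry (a segment of genome positions with an
exact per-position column array), so both query directions are resolved by
a binary search over segments or block offsets followed by an O(1) array
lookup.  Invariants enforced at build time: equal gapped lengths within a
block, non-gap counts matching the claimed genome interval, per-genome
disjointness of block intervals.  Positions not covered by any block map to
the `UNALIGNED` sentinel; columns where a genome is gapped or absent map
back to `GAP`.

## Annotation lifting

A gene whose interval lies within one block entry is lifted exactly (every
position of an entry's interval has a column, so the lifted interval is the
envelope of the two endpoint columns).  A gene spanning several blocks is
lifted to the single block holding the majority of its bases: a pan gene
occupies one row with one interval, so splitting genes across blocks would
break the "one gene, one cell" model; the majority block preserves most of
the signal.  Genes with no aligned base are dropped with a warning.  The
lifted strand is the annotation strand, flipped when the carrying entry is
reverse — i.e. orientation along the shared axis.

## Pan gene grouping

Two lifted genes are candidate orthologs when their super intervals share
at least `min_overlap` columns (default 1: any shared column creates a
candidate edge; sequence identity, not the overlap length, separates false
joins).  Connected components of this interval-overlap graph are found by a
single sweep over start-sorted intervals, which is exact on a line;
intervals shorter than `min_overlap` are isolated singletons and bypass the
sweep.

Within a component, groups are built by greedy agglomerative merging:
starting from singletons, repeatedly merge the two groups with the highest
average inter-group identity, allowed only when (a) their genome sets are
disjoint — a pan gene may contain at most one gene per genome, which is
what prevents paralog collapse — and (b) that average reaches
`identity_threshold` (default 0.5).  Ties break deterministically on
(smaller super start, genome roster index, gene id).  Average linkage is a
declared choice; minimum or single linkage would be equally defensible, and
the linkage is isolated behind one scoring expression.

Pairwise identity is Needleman–Wunsch global alignment (match +1, mismatch
−1, gap −2, via Biopython's `PairwiseAligner`) scored as matched columns /
alignment length; the pair is ordered canonically before aligning so the
value is symmetric.  Sequences are compared in annotation (sense)
orientation, so genes inverted in one genome — whether the aligner carried
the inversion as a reverse-strand block or left it inside a forward block —
still compare against the same coding sequence.  IUPAC ambiguity codes
other than A/C/G/T are collapsed to N.

Greedy merging is a heuristic: on adversarial similarity structure
(cross-genome conflicts arranged so the locally best merge blocks a
globally better pairing) it can be suboptimal relative to exhaustive
partition enumeration.  On realistically separated inputs — within-group
identity well above threshold, between-group well below, which is what
alignment of true orthologs produces — it attains the enumeration optimum;
the test suite checks exactly this regime (within-group identity drawn from
0.75–1.0, between-group from 0.0–0.40, threshold 0.5) on components of up
to 8 genes, where exhaustive enumeration is feasible.

Pan genes are ordered ascending by (super start, super stop, roster index)
and numbered `PG000001`… .  A consensus description is the most frequent
member description (ties: lexicographically first).

## Matrix model and curation algebra

With `n` genomes, a pan gene with `n` members is *core*, with one member an
*orphan*, otherwise *dispensable*; the three counts always partition the
row count.  Aggregation merges user-selected rows into one `AGN<serial>`
row, displayed as `AGN<serial> (k)` where `k` counts original constituent
rows (nested aggregations contribute their own counts).  The only
precondition is complementarity — pairwise disjoint member genome sets;
strand differences never block a merge, since orthologs legitimately change
strand through inversions.  The merged row sits at the position of its
first constituent, keeping SuperGenome order.

Every row carries a stable integer position key assigned at load;
aggregation gives the merged row the smallest constituent key and
deaggregation re-inserts constituents (retained verbatim inside the AGN
row) at their keys, so restoration is exact — byte-identical through the
pan-map writer.  Undo is a snapshot stack: each event pushes the prior row
list; undo pops it and *appends* a compensating event to the history rather
than truncating it, so the exported history is a faithful audit log and
replaying it on the freshly loaded matrix reproduces the current state.
AGN serials are monotone within a session; replay honours recorded ids.

## Candidate detection

A disrupted ortholog group appears as two nearby rows that are
complementary and share functional annotation.  `find_candidates` emits
pairs within a row-rank window (default 2 — "very close neighbourhood" has
no published number, and 2 covers the observed orphan-next-to-rest
pattern), that pass `can_aggregate`, and whose annotation matches per the
`require` mode: equal non-empty TIGRFAM ids, case-insensitively equal
consensus descriptions, or either.  Pairs are ranked by (row distance,
combined size descending, rank).  The number of core rows directly flanking
the pair is reported as an informational score (conserved context makes a
disruption more plausible) but never filters.  Chains of more than two
fragments are handled by repeated application.

## Rendering

Rendering builds a resolution-independent display list, serialised to
SVG 1.1 text, rasterised through Pillow (PNG/JPEG/TIFF at configurable
DPI), or emitted as a minimal self-contained vector PDF (Helvetica,
uncompressed streams).  A present gene is an up-pointing triangle for `+`
and down-pointing for `−` (the exact polygon is a fixed declared geometry);
absent cells stay blank.  Colour schemes: uniform presence colour; strand
(blue `+` / orange `−`); TIGRFAM, using 20 colours at hues `i/20`
(saturation 0.65, brightness 0.85 — the hue spacing is the fixed
requirement, saturation/brightness are configurable), assigned by a stable
MD5-based hash of the family id so figures reproduce across sessions
(collisions beyond 20 families are accepted).  Genes without an assignment
use the presence colour.  The optional group-size column encodes
classification: core blue, orphan red, dispensable linearly interpolated
from red (2 members) to blue (n−1).  Aggregated rows are highlighted.
Rendering is pure: identical matrix and config give identical SVG bytes.

## Synthetic data generator

`make_toy_dataset` builds toy genomes from gene families on a shared axis:
core families in every genome, private orphans, dispensable families on
random proper subsets.  Copies differ by substitutions only (2% per base),
so family blocks are gapless and the generator can write the *true*
alignment — it knows the homology — sidestepping any aligner.  Genes are
300–600 bp, spacers 40–80 bp, and a shared unannotated anchor region opens
the alignment.  Per-genome uncovered tails exercise unaligned positions.

Perturbations emulate the curation targets:

* **Inversions** (per multi-genome family copy, probability
  `inversion_rate`), in two styles chosen 50/50: an in-place gene inversion
  inside a forward block (annotation `−`, lifted strand `−`) and a
  whole-segment inversion carried as a reverse-strand block entry
  (annotation `−`, lifted strand `+`).  Both must survive grouping, which
  is why identity is computed on sense sequences.
* **Truncations** (`truncation_rate`): one copy's annotation is cut to 40%
  of the gene — the premature-stop outcome of a homopolymer insertion.  At
  the default threshold a 40% fragment falls below 0.5 identity against the
  full gene and splits off as an orphan next to its complementary group; a
  60% fragment stays above and keeps its group, which the tests assert as
  the truncation-robustness boundary.
* **Block splits** (`block_split_rate`): one genome's segment is torn out
  of its family block into a private block, emulating an erroneously
  aligned region; the copy cannot overlap its orthologs and becomes an
  adjacent orphan.

Truncations and block splits are recorded as planted disrupted pairs; the
candidate detector is required to flag all of them.

`make_synthetic_matrix` builds a matrix directly with an exact category
composition; the `saureus_like` preset uses the published 32-genome
composition (1846 core, 3848 orphan, 2953 dispensable = 8647 pan genes).

What the generator does **not** emulate: indels within genes, annotation
start/stop jitter between genomes, mobile elements and repeats, heuristic
aligner gap placement, and paralogous families.  Passing the end-to-end
recovery tests therefore shows the machinery is exact under substitution
noise and the planted rearrangements, not that grouping is robust to every
real-world alignment artefact — that is what the interactive curation layer
is for.

## Problem sizes and numerics

Test and acceptance runs use deliberately small instances chosen as the
smallest sizes that still exercise every code path: random alignments of
2–5 genomes and a few kilobases, components of ≤ 8 genes (the largest size
where exhaustive partition enumeration is a practical oracle), toy data
sets of 3–4 genomes with 5–8 families, and 30–200 repetitions per
stochastic suite.  All randomness is seeded; identity comparisons are exact
(rational match counts), and the only floating-point tolerance used is
1e-9 when comparing partition scores.  Degenerate inputs are defined
rather than rejected where a meaning exists: empty matrices render as
header-only canvases and summarise as zeros; genes without aligned bases
are dropped with warnings; strandless or ID-less GFF records are skipped
with warnings (strand is required for glyph orientation).

## Known limitations

* Block order on the super axis is file order; rearranged local blocks are
  not re-ordered by synteny.
* A gene spanning blocks keeps only its majority-block interval.
* Greedy resolution is heuristic (see above); components larger than a few
  dozen genes are quadratic in pair count.
* The richer of the two pan-map dialects is this package's declared column
  layout (id, super interval, consensus, per-genome triplets), not a claim
  about any external tool's exact file layout.
* Aggregated rows serialise with their AGN id but not their constituent
  tree; deaggregation is only available within the session that performed
  the aggregation (the exported history preserves the audit trail).
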