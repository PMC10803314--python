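# Methods

## Detection model

A PICMI-like locus is recognized by gene content and co-localization, not by
sequence similarity to a reference element. Genes are matched to roles purely
by domain labels supplied by an upstream annotator (Pfam accessions are
normalized case-insensitively with version suffixes stripped, so
`PF00589.25` ≡ `PF00589`): integrase (PF00589, PF00239, PF07508), AlpA-like
regulator (PF05930, PF12728), DUF3987/DUF5906 primase (PF13148, PF19263) and
Fis regulator (PF02954). Role hits on a contig are clustered so that
consecutive hits have at most `max_gene_gap` (default 5) intervening genes;
a cluster containing all required roles becomes one candidate, which makes
overlapping windows merge by construction. Within a cluster the reported
assignment is the *closest-packed* one: the injective role→gene assignment
with the smallest bp span that still satisfies the gap rule, ties broken
leftmost. The scan is order- and strand-agnostic.

`fis_policy` defaults to `mandatory` — the *fis* anchor must sit in the
window — because elements elsewhere than *fis* have not been observed; the
`optional` policy (attach a co-localized *fis* when present) is retained for
exploratory screens of alternative integration sites. The gap default of 5
intervening genes is the conventional co-localization window of
MacSyFinder-style rule engines; it is a free parameter, not a measured
constant.

Genomes whose mandatory roles co-occur only across contigs (draft
assemblies, split decoys) yield a merged candidate anchored on the contig
carrying most roles; the `cross_contig` filter flag then excludes it, which
operationalizes the published exclusion of elements with *int*, *alpA* and
*fis* on different contigs.

### Filters

Each candidate receives zero or more flags; only flag-free candidates are
retained, flagged ones are reported for audit:

- `other_family`: any gene in the span labelled *terS*, *sid*, *ppi* or
  *psu* (hallmarks of PICI/cf-PICI/P4/PLE satellites, matched on product
  label, case-insensitive).
- `cross_contig`: int/alpA/fis hits on more than one contig.
- `bad_fis_anchor`: global protein identity (BLOSUM62, gap open −11 /
  extend −1, gaps counted in the denominator) of the anchor to a
  user-supplied Fis reference below 0.30, or below its identity to any
  supplied decoy anchor. The 0.30 floor is a design choice: well below
  genuine Fis orthologs (Fis is highly conserved) and well above chance
  identity of unrelated proteins.
- `oversize`: span above `max_element_len` (default 50 kb).

When several candidates survive in one genome, all are kept, ranked smallest
span first (a minimalist prior), and a warning is emitted — one element per
genome is the expected outcome, never silently enforced.

## Boundary extraction

Integration at *fis* leaves two identical direct repeats; the element is
extracted from the first base of *fis* to the far edge of the repeat copy on
the int-distal side. The repeat finder takes the longest exact shared
substring between an anchor window at the *fis* 3′ end and a search window
past *int* (600 bp windows by default), located by binary search on length
(shared-substring existence is monotone in length); ties break by the pair
spanning the largest interval, then leftmost. Minimum length 15 bp, exact
match only: the observed repeat is a 17 bp exact pair and no mismatch
tolerance is reported, and at 15+ bp chance matches in 600 bp windows are
vanishingly rare. Without a repeat, extraction falls back to
`[fis start, int end + 1000 bp]` and records the absence. Sequences are
reported fis-forward (reverse-complemented when *fis* is on the minus
strand).

Small-ORF scanning reports every ATG-initiated, stop-terminated reading
frame of 30–59 aa in all six frames whose overlap with annotated genes is
≤ 30 bp. All qualifying ATG–stop pairs are reported (not only the most
upstream start per stop), which keeps the operation equivalent to a naive
six-frame enumeration and lets planted ORFs be matched exactly.

## Element comparison

Pairwise nucleotide identity is end-to-end global alignment (match +1,
mismatch −1, gap open −4, extend −1) with identity = matches / alignment
columns, gap columns included — elements are compared over their full
extracted span, so terminal and internal indels both dilute identity.
Subfamilies are connected components of the graph with edges at identity
≥ 0.90 (single linkage; complete linkage available). The published grouping
does not state how pairwise identities became clusters; single linkage is
the weakest assumption consistent with "pairwise identity ≥ 90% within
families" and is checked against exhaustive partition enumeration in the
tests. The threshold comparison is `>=` with a strict-mode switch.

Gene families are reciprocal best hits under local protein alignment
(BLOSUM62, −11/−1): a hit is valid at identity ≥ 0.20 with ≥ 0.50 coverage
of both sequences; the best hit per (query, target proteome) is chosen by
score, ties by identity then lexicographic id, making the output invariant
to input order. RBH edges are closed into families by connected components;
unpaired proteins are singletons. Small ORFs and pseudogenes are excluded
from family construction.

The *int*-neighbor call examines genes between *alpA* and *int* on the
extracted element: overlap of ≥ 1 nt with *int* is `iolg` (overlap motif
reported 5′→3′ on the fis-forward strand; a 4 nt overlap is `ATGA`, the
*int* start codon read through the neighbor's stop), a non-overlapping gene
is `icg`, no gene is `absent`.

## Packaging quantification

`hitchhiker_fraction` normalizes read counts to depths (reads/bp), divides
the satellite depth by the concatemer copy number to get particle
equivalents, and reports (a) the full-precision satellite:helper odds
`(N_s·L_h)/(N_h·L_s·c)` with the derived particle fraction `odds/(1+odds)`,
and (b) the printed-convention integer percentage computed with two-decimal
intermediate rounding and final truncation, which reproduces published
arithmetic digit for digit (16 from depths 13.26/17.71 at 8 copies).
Displays default to full precision.

`headful_copy_number` returns the k ≥ 1 minimizing |k·L_s − L_h|, ties to
the larger k: a headful mechanism packs until the capsid is full, so
overshoot is the physical tie-break.

Read classification is alignment-based so the same operation serves short
and long reads: a read is anchored to a reference when ≥ `min_anchor`
(default 50) of its bases place there at ≥ 70% identity under infix
alignment (edlib, both strands); chimeric reads are caught by a coarse
prefix/suffix split scan. Reads anchored to both references are hybrid;
neither, unassigned. The satellite reference should tile the unit at least
twice so concatemer-junction reads place cleanly.

Long reads are placed on an artificial tandem reference of 13 unit copies
(any count covering the longest read is equivalent); the start phase is the
placement offset modulo the unit length, strand-normalized. Reads below a
70% identity floor are dropped and counted. Extremity randomness is a
chi-square goodness-of-fit of phases against uniformity over 20 equal bins
of the unit — chosen over Kolmogorov–Smirnov because phases are circular and
binning on the unit sidesteps the origin choice. p ≥ 0.05 reads
"random-extremities (pac-like)", otherwise "fixed-extremities (cos-like)";
fewer than 20 reads is an error (underpowered).

## Synthetic data

The generator emulates the reference system at its published scales: a
6,110 bp element with gene order fis–up2–prim–up1–alpA–iolg–int flanked by
17 bp exact repeats, a 47,851 bp helper, an 8-copy concatemer, and an
*iolg*/*int* overlap of 4 nt (configurable to 0/1/13). Planted genes are
random ATG…stop ORFs with fixed per-role lengths (e.g. integrase 1,203 nt,
primase 903 nt, regulators ~300 nt); detection operates on their domain
labels while alignment-based operations see their sequence, so both
pathways are exercised. One large non-coding spacer between *prim* and
*up1* absorbs the length budget and hosts optional planted small ORFs.
Sentinel bases adjacent to the planted repeats prevent chance single-base
extensions, so the planted pair is exactly the maximal repeat. Background
composition is uniform ACGT with unlabeled filler genes; GC bias,
transcription signals and sequencing error are deliberately absent — passing
recovery tests therefore demonstrates the correctness of the logic under
the model's own assumptions, not robustness to noisy annotations or errored
reads.

Decoy loci exercise each filter: an other-family locus (co-localized cores
plus a *terS*-labelled gene), scattered cores separated by more than
`max_gene_gap` filler genes, and an element split across two contigs. The
cohort generator cycles genomes through true-element, element-plus-decoys
and decoy-only patterns on both strands, sharing one host *fis* anchor.

Divergence-controlled variants for clustering tests mutate a common
ancestor: subfamily prototypes at the between-divergence (default 0.20),
members at the within-divergence (default 0.03) from their prototype; 10%
of mutation events are 1–3 bp indels, the rest substitutions. Two members
at 3% each sit near 0.93–0.94 pairwise identity, comfortably above the 0.90
threshold, while prototypes 20% diverged from a common ancestor fall near
0.65, far below it.

Read simulation draws each particle's content (satellite concatemer with
probability f, helper otherwise) implicitly through the per-read satellite
probability f·c·L_s / (f·c·L_s + (1−f)·L_h); chimeras occur at 1e−4 of
reads (loosely motivated by the published 16 hybrid in ~743k reads).
Long-read phases are uniform over the unit in pac mode and fixed at 0 in
cos mode. All outputs are byte-deterministic in (config, seed).

## Problem sizes and numerical choices

The bundled acceptance computations use 50 simulated genomes for detection
recovery, 5 subfamilies × 2 members at the full 6,110 bp element length for
clustering, 100,000 reads for fraction recovery and 100 replicates × 500
phases for test calibration — sizes at which every stochastic check is
stable across seeds. Identity computations are exact dynamic programming
(Biopython's PairwiseAligner); read placement uses edlib's bit-parallel
edit-distance alignment. Degenerate inputs (empty genomes, zero candidates,
zero elements, empty read sets) return empty results rather than errors;
genuinely contradictory inputs (inverted regions, empty references,
reads longer than the concatemer reference) raise `ValueError`.

## Known limitations

- Domain labels are trusted as given; no HMM search is performed, so
  detection quality is bounded by the upstream annotation.
- The repeat finder is exact-match; a polymorphic attL/attR pair longer
  than 15 bp with internal mismatches would be truncated to its longest
  exact block.
- Hybrid-read calling uses split infix alignment, not junction-resolved
  breakpoint mapping; it counts dual-anchored reads, which is the weaker of
  the two published interpretations.
- The extremity test bins circular phases; with very few long reads the
  chi-square approximation is the limiting factor, hence the 20-read floor.
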