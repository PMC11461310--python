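# Methods

This note documents the models, procedures and numerical choices behind
`endomine`, and what the synthetic studies do and do not demonstrate.

## The discovery model

The pipeline assumes the following generative situation: a host genome was
assembled from long reads of a mixed DNA sample (host plus an intracellular
bacterial symbiont), and the assembler concatenated the symbiont's
chromosome into a host scaffold, bridging the impossible joins with runs of
N. Three consequences are observable and drive the three evidence stages:

* the symbiont-like span matches bacterial references while the flanks match
  the host (homology screening / scaffold anatomy);
* read depth over the span differs strongly from the flanks, because the two
  molecules were present at different copy numbers in the sample (coverage
  origin test);
* the span derives from a circular molecule, so reads crossing its
  artificial end recover the missing sequence and a terminal overlap
  (circularization).

None of the stages requires the symbiont to be *under*-covered relative to
the host; the verdict rule accepts discordance in either direction and
records the direction in its evidence notes, since enrichment protocols can
push symbiont depth either way.

## Homology screening

Screening re-creates two-step nucleotide classification: queries are first
scored against a symbiont panel (retention step), then against a broad panel
holding symbiont *and* non-symbiont groups; each query is labeled by the
group of its single top broad-panel hit, with score, then identity, then
subject id as deterministic tie-breakers. Queries with no broad-panel hit
are `unclassified`.

The aligner is seed-and-extend: exact k-mers (default k = 15; `N` is
excluded from seeds and never matches) shared between query and subject are
clustered by diagonal, and each cluster is resolved by an affine
Smith–Waterman (Gotoh) pass over a rectangle around the cluster. Pairs small
enough that the full rectangle is cheap (≲ 1.5 kb each) are aligned over the
whole rectangle, which makes the top score exactly the full-DP optimum
whenever at least one seed exists. The scoring scheme is fixed to match +2,
mismatch −3, gap of length L costing 5 + 2·(L−1) — the classic nucleotide
megablast-style defaults — because the original analyses' alignment
parameters are not recoverable; the scheme is declared rather than inferred,
and every threshold (`min_score` 50, `min_identity` 80%) is configurable.

Scaffolds longer than 50 kb are screened in 10 kb windows with 1 kb overlap
(both configurable; the bundled small-scale studies use 1 kb windows so that
region boundaries resolve inside a 15 kb scaffold). Both strands are
searched; minus-strand hits are reported in forward coordinates with a
strand flag.

COI-based host identification reuses the same aligner against a
species-labeled barcode panel, iteratively masking each reported region so
that a second, more divergent barcode copy (a mixed-sample signature)
surfaces with its own best species instead of being shadowed by the first.

## Scaffold anatomy

Window labels are painted onto a per-base array (symbiont > host >
unclassified on overlaps), N-gap intervals override everything, short
unclassified runs (< 2 windows) between two same-label segments inherit that
label, and the largest symbiont stretch — internal gaps count as continuity,
not interruption — becomes the reported span. Finally the span's outer
boundaries snap to an abutting gap's inner edge when one lies within
`snap_distance` (default: one window). The rationale: homology windows
cannot resolve a junction below window granularity, but the N-gap edge is
base-exact, so the gap edge is the better boundary estimate wherever the two
disagree by less than a window. Coordinates are 0-based half-open
internally, 1-based inclusive in every report, and 0-based half-open in BED.

## Coverage and the origin verdict

Pileup depth counts, per reference base, the records whose CIGAR consumes
that base with M/=/X; D and N consume reference without depth; I/S/H consume
none; unmapped, secondary (0x100) and supplementary (0x800) records are
skipped. Excluding deletion positions from depth is a declared convention —
the alternatives differ negligibly at the depths involved but a testable
rule is needed.

The origin statistic is R = (symbiont-span mean) / (unweighted mean of the
two flank means). The unweighted mean mirrors how flank depths are naturally
reported as two separate values; it also makes R insensitive to unequal
flank lengths. Verdict thresholds default to (0.5, 2.0): R outside the band
plus gap-flanked junctions ⇒ ENDOSYMBIONT; R inside the band with seamless
junctions ⇒ HGT_CANDIDATE; any other combination ⇒ AMBIGUOUS. Zero flank
coverage yields AMBIGUOUS with a note rather than an exception.

## Circularization

Gap filling replaces de-novo re-assembly with a specified, testable
consensus: reads are anchored to the terminal 200 bp window of the region
(`anchor_len`) by exact 21-mers on a single diagonal, verified at ≥ 90%
gapless identity over the overlapping stretch, and their portions beyond the
terminus are stacked into a column-wise majority vote (ties break
alphabetically, deterministically). The extension stops at the last column
with `min_spanning_reads` (default 3) coverage; fewer than that many
anchored reads is a distinct no-fill signal. Anchoring by seeds inside the
window, rather than by one exact 200-mer, keeps the anchor usable at
realistic read error (an error-free 200-mer survives in <2% of reads at 2%
per-base error, while an error-free 21-mer survives in ~65%).

Terminal-overlap detection is gapless with mismatches only (defaults:
`min_overlap` 50 bp, `min_identity` 95%), scanning suffix/prefix lengths
from the longest candidate down — terminal repeats produced by re-assembling
one circular molecule differ only by sequencing error, so gaps would only
admit spurious low-complexity matches. An all-one-letter input trivially
matches at the maximal length and is returned flagged `low_complexity`.
Circularization trims exactly one copy of the overlap; the closed genome's
length plus the merged overlap equals the linear input length by
construction.

Rotation is canonicalized to the lexicographically least rotation (Booth's
algorithm) unless an anchor sequence is supplied, in which case the rotation
starts at the anchor's best plus-strand hit and falls back to the least
rotation when the anchor does not align. All comparisons against a reference
circle are rotation-invariant (`is_rotation`).

## Genome features and pseudogene indicators

GC content is 100·(G+C)/(A+C+G+T) with ambiguous bases excluded from both
counts (a declared convention). GC skew is (G−C)/(G+C) in sliding windows,
default 10 kb window / 1 kb step; windows without G or C report 0 with a
flag. Coding density is the union of CDS intervals over the genome length,
strands pooled, overlaps counted once. Gene-class counts come from the
annotation: tRNA/rRNA by feature type; hypothetical vs known proteins by the
product string `hypothetical protein`; ankyrin/transposase/phage by
configurable case-insensitive keyword lists ({ankyrin}, {transposase},
{phage, prophage}).

Pseudogene indicators are called against an intact relative's proteome, not
by re-implementing any particular annotation tool. Each reference protein is
located by exact 8-mer peptide seeds in all six reading frames; seed hits
cluster by (strand, nucleotide diagonal). The cluster structure is the
diagnosis:

* **frameshift** — consecutive clusters whose diagonals differ by a
  non-multiple of 3 (an in-frame indel, divisible by 3, is not a frameshift);
* **internal stop** — a stop codon inside a cluster's translated span, each
  cluster translated in its own frame (so a frameshifted gene is not also
  charged with the garbage stops downstream of the shift);
* **missing start / missing stop** — the codon at the mapped reference start
  is not ATG/GTG/TTG, or the codon after the mapped reference end is not
  TAA/TAG/TGA (translation table 11); judged only for frame-consistent loci,
  since a frameshift already destroys the downstream frame.

A gene with at least one indicator counts once toward the pseudogene total;
per-indicator counts may exceed it. A reference protein with no locus at all
is recorded as missing — absence is not pseudogenization. On real genome
pairs these counts approximate, and are not expected to equal, counts from
heuristic pseudogene finders with undocumented length and dN/dS filters.

## Pangenome and enrichment

Cross-genome protein pairs are scored with the same seeded aligner (5-mer
peptide seeds, identity-based scoring); edges need ≥ 70% identity and ≥ 75%
coverage of both lengths. The 70% default (rather than a within-species
~95%) reflects clustering across deeply diverged symbiont lineages.
Bidirectional-best edges per genome pair form a graph whose connected
components are the clusters; a component holding two proteins of one genome
is split by dropping its weakest edge (score, identity, coverage, then a
deterministic id tie-break) until one-per-genome holds. This is a
transparent stand-in for production pangenome pipelines; it reproduces their
*logic* (BBH + components + paralog splitting), not their binaries.

Enrichment is the classic one-sided Fisher / hypergeometric test per GO
term: `expected = annotated·|study|/|universe|` exactly, and
`p = P(X ≥ significant)` for X ~ Hypergeom(N, annotated, |study|)
(scipy's survival function). P-values are reported raw, sorted ascending;
GO-graph-weighted decorrelation (topGO's weight01) is deliberately out of
scope, so p-values on real data are comparable in spirit but not numerically
to weight01 outputs — the Expected column is the arithmetically checkable
one.

## The synthetic-data generator

The generator emulates the discovery's observable structure at 1/100 scale
(its defaults): a 10,780 bp circular symbiont genome at GC 0.33, inserted
linearly minus its final 262 bp, 100 bp N-gaps at both junctions, host
flanks of 1,600/2,500 bp at GC 0.42, host depth 60X vs symbiont depth 12X,
and panels derived from the true circle and flanks at 2% divergence.
Composition is i.i.d. per base with P(G)=P(C)=gc/2 — no codon structure, no
repeats — which suffices for every downstream test because no stage exploits
higher-order composition. Read lengths are 500 bp plus a geometric excess
(mean default 1,500 bp), truncated at the template; only substitution errors
are simulated in reads, so alignment records keep all-M CIGARs and remain
truthful placements. Symbiont reads are drawn from the *circle* (wrapping),
then placed on the scaffold the way a mapper would place them: the portion
inside the embedded span aligns, the rest soft-clips, and reads starting in
the withheld terminal region land at the span start with a leading clip.

What passing tests on this generator demonstrate: the pipeline's logic —
boundary recovery, ratio estimation through the full read→pileup path,
circle closure, lesion classification — is correct under controlled noise.
What they do not demonstrate: robustness to real long-read error profiles
(indels, chimeras), repeat-induced mis-seeding, multi-copy or plasmid
symbionts, or host mixtures (the generator models one host template; mixed
isolates with divergent barcodes are left to explicit test construction).

GO universes annotate genes independently per term with per-term prevalence
drawn Uniform(0.05, 0.30); the planted term elevates study-set odds by a
factor. With `planted_odds = 1` no term is enriched by construction. Null
calibration of the discrete hypergeometric test requires annotated counts
large enough that the test's achievable levels sit close to nominal: the
calibration studies use a 4,000-gene universe with a 10% study fraction,
where the rejection rate at p < 0.05 lands near 4–4.5% (the residual deficit
is the unavoidable conservativeness of a discrete test). At small universes
the same test is markedly conservative — that is a property of Fisher's
test, not a bug.

## Study sizes used by the bundled checks

* End-to-end mining: the default 1/100-scale study (seed-controlled),
  error-free reads — recovery is exact and is checked exactly.
* Depth-ratio recovery: symbiont 40 kb between 30 kb flanks, 600 bp mean
  reads, ratios 0.05–20; with reads drawn to a fixed total-bases target the
  region means are tight and the estimate lands within a few percent,
  comfortably inside the 10% acceptance band. (Choosing sizes from the
  fluctuation formula var(mean depth) ≈ depth·E[L²]/E[L]/region keeps the
  band at several σ.)
* Noisy-circle recovery: 2% substitution reads at ≥20X close the circle with
  ≤ 0.2% mismatches; the consensus columns are majority votes over ≥ 3 reads.
* Pseudogene battery: 25 seeded genomes × 4 lesion types, each lesion
  yielding exactly its own indicator.

## Known limitations

* The aligner guarantees DP-optimal scores only when a seed exists and, for
  large pairs, within the clustered rectangles; a homology with no shared
  15-mer (≳ 7% divergence in the worst case) can be missed. This matches the
  screening use case, where references within a few percent exist by design.
* Gap filling assumes substitution-dominated read error; heavy indel error
  would shift anchor diagonals and erode the column-wise vote.
* The origin test is a decision rule, not a statistical test: no uncertainty
  is attached to R, and depths are not GC-corrected.
* Ortholog clustering is greedy per component; pathological near-tie edge
  configurations can split differently than an exhaustive optimum would
  (ties themselves are broken deterministically).
* Enrichment treats GO terms independently (no graph structure), so nested
  terms co-enrich.
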