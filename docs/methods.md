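# Methods

This note documents the models, conventions and defaults behind each
stage, what the synthetic generator does and does not emulate, and the
design choices made where the problem was genuinely open.

## Coordinates, digestion, overlap

All coordinates are 0-based half-open internally; 1-based conversion only
happens at browser-text export. In-silico digestion cuts at the match
start of the recognition site (the blunt convention for a 4-cutter such as
MboI/GATC); `N` never matches; zero-length fragments are suppressed, so
fragment lengths always tile the chromosome exactly. Fragment ids are
genome-wide consecutive integers in genomic order so inter-fragment
distances can be taken between id-adjacent midpoints. Interval overlap is
"at least one shared base" everywhere (`[a,b)` vs `[c,d)` overlap iff
`a<d and c<b`); no reciprocal-fraction requirement is applied anywhere.
The overlap index is a sorted-start array with a prefix maximum of ends
(O(log n) for any-overlap, vectorised candidate scans otherwise); at the
scales this package targets (10^4–10^6 intervals) this outperforms a
general interval tree and needs no extra dependency.

## Pair classification

Decision order: (1) either MAPQ below `mapq_min` (default 1) → low-MAPQ;
(2) different chromosomes → valid trans; (3) both ends in one restriction
fragment → artifact, split by orientation after canonically ordering the
mates by coordinate: inward (+/−) = dangling end, outward (−/+) =
self-circle, equal strands = dumped; (4) different fragments closer than
`min_separation` (default 1000 bp) → too close; (5) valid cis. Canonical
mate ordering makes classification invariant under mate swap, which the
raw file order does not guarantee. "Distance between two fragments" is
taken between fragment **midpoints** by default because it is stable under
the read's position within the fragment; a nearest-edge mode is provided.
Exact-coordinate PCR deduplication is on by default (artifact-prone
protocols are duplicate-prone; a flag disables it).

## HOCI calling

Hubs are called as sharp 1D peaks in valid-pair **end** coverage; both
ends of every valid pair contribute, since a hub manifests as a pile-up of
ligation-product ends regardless of where partners map. Coverage is
binned at 50 bp. Each non-empty bin is tested against a Poisson local
background λ = max(genome-wide rate, mean rate in 5-kb and 20-kb centered
windows), with Benjamini–Hochberg control at q ≤ 0.05 over tested bins
genome-wide. Significant bins are merged within 200 bp (narrow mode;
broad mode merges within 4×200 bp before width filtering), peaks shorter
than 150 bp are dropped, and the summit is the highest-count bin. This is
a deliberately simple MACS-style caller: the zero-inflated
negative-binomial machinery used by some FAIRE-seq pipelines is not
reproduced — the acceptance surface here is planted-hub recovery, and on
the generator's default conditions the caller attains recall and
precision ≥ 0.9 (in practice 1.0). Saturation analysis downsamples valid
pairs without replacement at given fractions and re-calls peaks; at
extreme downsampling the peak count can transiently *rise* as single hubs
fragment into several short peaks — a property of any merge-based caller
worth knowing when reading saturation curves.

## HOCI classification and statistics

Promoter HOCI: overlaps an H3K4me3 peak **and** a promoter window.
Enhancer HOCI: otherwise, overlaps both H3K4me1 and H3K27ac peaks.
Everything else: other. Promoter precedence resolves the ambiguity of
regions carrying all marks. The promoter window is strand-aware and
upstream-only by default — 2 kb upstream of the TSS through the TSS —
with a symmetric ±2 kb option. Occupancy counts distinct DNA-binding
factor peak sets overlapping each HOCI (a factor with several overlapping
peaks counts once). Venn-style overlap reports count elements sharing
≥1 bp with the other set; the association test is a one-sided Fisher
exact test on genome bins (1 kb default) labeled by membership in each
set — a coarse but assumption-light genome-background null.

## Interaction network and pair categories

A read end maps to a HOCI by point containment of its 5' coordinate
(HOCIs are non-overlapping after merging; overlapping input is an error).
Edges are unordered HOCI pairs weighted by raw bridging-pair counts — no
distance-decay normalisation, since the drawn quantity is unique valid
pairs. Same-HOCI pairs count toward node interaction totals but form no
edges. Pair categories follow strict precedence: both ends promoter →
promoter–promoter; both enhancer → enhancer–enhancer; one of each →
promoter–enhancer; else one promoter end → promoter-related; else one
enhancer end → enhancer-related; else other. Distance summaries use the
exact median (lower of the two middle values for even n) of |pos2−pos1|
over cis pairs; empty categories are reported as absent, never zero.

## Gene typing and expression

Per condition: *hub* if the promoter window overlaps any HOCI;
*interacting* if at least one valid pair (`min_link_pairs`, default 1)
joins the promoter window to any HOCI; else *dissociative*. "Expressed"
means RPKM strictly above 0.5. Cross-condition comparison categorises
genes as same-type / hub↔dissociative / other-change, flags "promoter
HOCI changed" genes (promoter overlaps a HOCI in exactly one condition)
and compares |log2FC| of changed vs unchanged genes among down- and
up-regulated genes separately (one-sided Mann–Whitney). Log fold changes
use a pseudocount of ε = 0.01 RPKM.

## Super-enhancers and broad domains

Constituent enhancers fully contained in a TSS ± 2 kb window are removed
(classic ROSE behaviour; an any-overlap mode exists), the rest are
stitched transitively at gaps < 12.5 kb, and stitched regions are ranked
by total background-subtracted signal (rpm·bp, negatives floored at 0).
With rank and signal scaled to [0,1], the slope-1 tangent point of the
ascending convex curve is found exactly as argmax(x − y), ties broken to
the rightmost index; entries strictly to the right are super-enhancers.
On y = x² over 1001 points this lands at index 500 with 500 supers; a
linear curve yields none. Broad domains are the widest ceil(5%·N) peaks
(ties by genomic order); a fixed `min_width` mode (e.g. 4 kb) is also
provided.

## Contact matrices

Cis pairs are binned per chromosome at 40 kb into dense symmetric
matrices. ICE balancing masks the lowest 2% of coverage bins, then
repeatedly divides rows/columns by their mean-normalised marginals until
the coefficient of variation of unmasked row sums drops below 1e-4 (≤100
iterations); weights satisfy balanced = W·raw·W up to scale, zeros stay
zero, and the result is scale-equivariant. Compartments: observed/expected
by per-diagonal means (diagonals with no unmasked entry skipped), Pearson
correlation across unmasked bins, first eigenvector of the correlation
matrix; the sign is oriented so bins richer in a reference track (HOCIs
or genes) are positive = A. A structureless matrix (top eigenvalue ≈ 0)
is flagged unreliable rather than labeled. Domain boundaries use the
insulation score (mean contact in a `window × window` square crossing
each bin, default 10 bins): local minima whose depth relative to the
lower flanking maximum exceeds `delta_threshold` of the mean score.
Boundary–HOCI enrichment is observed HOCI midpoint-bins in boundaries
versus circular permutations of HOCI bin positions (fold + permutation
p-value). Insulation boundaries are a deliberate, clearly-simpler
substitute for any specific TAD caller: the claims tested here are
boundary-enrichment statements, for which insulation minima suffice.

## Synthetic generator

Defaults define the study conditions: 2 chromosomes × 5 Mb of uniform
random sequence (a GATC site every ~256 bp), 40 hubs, 200,000 read pairs,
500 genes, seeded everywhere; generation takes a few seconds. Hubs are
laid out in four-hub modules (two promoter + two enhancer hubs) carrying
exactly one promoter–promoter, one enhancer–enhancer and one
promoter–enhancer link whose separations are **stratified quantiles** of
a log-normal around the configured medians (44/13/117 kb, σ = 0.15), so
the realized per-category median sits at the configured value by
construction rather than by luck; 8 standalone "other" hubs have no
links. Artifact pairs (10% dangling, 10% self-circle, 10% same-strand,
5% too-close, 5% low-MAPQ) are placed on real restriction fragments of
the synthetic genome so classification is exercised genuinely. Non-
artifact pairs split 55% background / 30% hub–hub / 12% hub–background /
3% promoter-link. Background cis distances follow P(d) ∝ d^−α (α = 1) on
[2 kb, 2 Mb], sampled distance-first with the left end uniform in
[0, L−d] so the distance law is exact and testable by a KS test against
the analytic CDF. Compartments are alternating 500-kb A/B blocks; hubs
land in A blocks with probability 0.8 and background pairs prefer
same-label ends without altering their distance (the preference only
re-draws the placement, not the separation). Gene types are planted
directly: hub genes' promoters reach into promoter hubs, interacting
genes receive ~20 promoter→hub link pairs each, and dissociative gene
promoters are exclusion zones that stray ends never enter — the planted
truth is exact by construction, so typing errors measure the pipeline,
not the generator. Expression is log-normal with type medians 20/5/0.2
RPKM (σ = 1), generator knobs chosen to give the expected hub >
interacting > dissociative ordering with realistic overlap. The
two-condition bundle removes promoter hubs until ~50 hosted genes are
affected, silences those promoters in condition B and scales the
affected genes' expression down 4× (multiplicative noise σ = 0.2 on all
genes).

What the generator does **not** emulate: mappability and GC biases,
copy-number variation, chimeric/multi-mapping reads, overlapping or
nested regulatory elements, trans-chromosomal structure, and
replicate-level variability. Passing tests therefore demonstrate the
correctness of the algorithms under the stated data model, not robustness
to every artifact of real libraries.

## Problem sizes and numerics

Default test/analysis sizes (2 × 5 Mb, 200k pairs, 40 hubs; 200-bin
matrices for balancing checks; 100-bin block models for compartments)
were chosen so the full suite and the acceptance script each run in tens
of seconds on one CPU while leaving the statistical checks well-powered.
Numerical choices: Benjamini–Hochberg ties broken by genomic order;
Poisson tail probabilities via the survival function (no normal
approximation); eigendecomposition via `numpy.linalg.eigh` on the dense
correlation matrix; ICE tolerance 1e-4 on the row-sum CV; permutation
p-values use the add-one estimator (1+hits)/(1+n).

## Known limitations

- The peak caller's broad/narrow modes are reported separately; no
  reconciliation of the two is attempted.
- The Fisher genome-bin null ignores bin-level covariates (GC,
  mappability); on real data a matched-background null would be stronger.
- Trans contacts are carried through filtering and networks but matrices
  are cis-only.
- `.hic`/`.cool`/bigWig binary formats are out of scope; all I/O is plain
  text (FASTA, BEDPE, BED/narrowPeak, TSV, bedGraph, COO).
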