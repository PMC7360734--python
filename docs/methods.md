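# Methods

This note documents the statistical procedures, defaults and design
choices behind `ervreg`, and what the synthetic validation does and does
not demonstrate.

## Coordinates and overlap semantics

All intervals are 0-based half-open internally. BED/narrowPeak pass
through unchanged; RepeatMasker `.out` (1-based inclusive) and GTF
(1-based inclusive) are converted at the I/O boundary. Overlap means
>= 1 bp in half-open semantics; strand is ignored for all peak-element
intersections and honoured only where transcription direction matters
(TSS derivation, splice-into-gene checks). The repeat BED dialect keeps
the family label in the BED name field and adds an optional seventh
column with a stable element id so that annotation, FASTA sequences and
downstream tables join losslessly.

## The permutation null

The enrichment null re-places each peak independently, length preserved,
uniformly over all genome positions where it fits entirely outside the
excluded (unmappable) regions. Placement is genome-wide — chromosome of
origin is not preserved — weighted by the number of valid start
positions per gap; a `per_chromosome` flag restores per-chromosome
placement for users who prefer that null. Placed intervals may overlap
each other (independent placement, the common shuffle semantics).
Within a sample, one set of `n_shuffles` placements serves every family:
this is ~F-fold cheaper than per-family shuffling and gives the null
counts a coherent joint distribution across families. Determinism: all
draws flow from one `numpy` Generator seeded by the caller.

The empirical p-value is add-one and two-tailed,
`p = min(1, 2*min((1+#{null>=obs})/(N+1), (1+#{null<=obs})/(N+1)))`, so
it is never zero and never below `1/(N+1)`. At `N=100` the rule's
granularity caps the attainable level near 0.04 (less with ties in
small-count families); calibration tests therefore compare the realised
rejection rate both against the nominal 5% upper bound (no inflation)
and against the discrete rule's own attainable level, estimated by Monte
Carlo from pooled null counts. Fold is `observed / max(null_mean, eps)`
with `eps = 0.5/n_shuffles`; a zero null mean is flagged rather than
reported as an infinite fold.

Filters follow the published convention: per-sample enrichment requires
p < 0.05, fold > 2 and more than 20 distinct copies overlapped ("copies"
is read as distinct elements, not peak count); family selection requires
enrichment in >= 1 cell line and in strictly more than 10% of disease
samples. No multiple-testing correction is applied at this stage (raw
p < 0.05, as published); correction appears only in the TF/motif module.
The copies filter is evaluated per sample; a pooled variant across
samples can be obtained by summing the overlap matrix.

## Heterogeneity

The element x sample matrix is binary (element overlapped by >= 1 peak).
Pearson correlation on binary indicators (the phi coefficient) is the
default; Jaccard is offered. The mutation comparison uses the median
within-mutated pairwise correlation minus the median within-wild-type
correlation, with between-group pairs in neither set. Significance comes
from permuting mutation labels over samples — not over pairs — because
pairwise correlations sharing a sample are dependent; label permutation
is exact under the exchangeable null. The test itself is this package's
construction: the original observation was reported qualitatively, with
no named test. One-sided, add-one, default 10,000 permutations.

## Chromatin states

Features are overlap fractions per element: for each of the four marks
and each group (disease, differentiated), the fraction of that group's
samples whose peak set overlaps the element — an 8-vector in [0,1]^8.
"Marked" means overlap in at least two disease samples (threshold
2/n_disease as a fraction). The state rule gives H3K4me3 precedence
(promoter-like), then H3K4me1+H3K27ac (active enhancer), H3K4me1 alone
(primed enhancer), H3K9me3 (heterochromatic), else unmarked; the rule
table is exhaustive over all 16 indicator combinations. Clustering is
standard k-means (k-means++, Euclidean, 10 restarts); k is configurable
with default 6 — the source analysis does not state its k — and an
inertia sweep ("elbow" table) is emitted so users can choose. Cluster
labels are renumbered by descending mean disease H3K27ac fraction, which
makes labels deterministic and stable under row reordering.

## Promoter discovery

Only multi-exon transcripts count as spliced evidence; unstranded
transcripts are rejected. TSS is the first base of the first exon (+) or
the last base of the last exon (-). A TSS hits an element when
`start <= tss < end`. Cross-sample identity is element-level: activity
in different samples is matched by (element, strand), not by transcript
structure, because assembled exon chains vary between samples; a
stricter first-splice-site match would only shrink the call set.
Disease-specific promoters need >= 2 disease samples and zero
differentiated samples with a TSS in the element. "Splices into an
annotated gene" requires a downstream exon (in transcription order)
overlapping an annotated exon on the same strand.

## Gene association

Genes pair with elements when the gap between spans is <= 50 kb (0 on
overlap); whole gene spans are used rather than TSSs, with TSS distance
available as an option. Expression is consumed on a log2 (vst-like)
scale, so the "> 4-fold" flag is `mean_pos - mean_neg > 2` together with
`mean_pos > 0`; the positivity condition is applied to the DHS+ group
mean. Group-level summaries split genes by their nearby elements' status
(open in >= 2 disease samples and also in differentiated cells / disease
only / closed), with a gene near several elements assigned once, highest
class first. Contrasts with an empty DHS+ or DHS- side are returned as
undefined and never flagged.

## TF and motif analysis

TF enrichment per family compares elements overlapped by TF peaks
against one length-preserving shuffle of the elements (same engine as
the peak null; the published description uses a single shuffled
control). The 2x2 table (bound/unbound x real/shuffled) gets a
two-sided Fisher exact test, with a Haldane-Anscombe corrected odds
ratio for degenerate tables; Benjamini-Hochberg runs across the whole
TF x family grid ("corrected p" is not otherwise specified at the
source). A TF is selected for a family at q < 0.05 with >= 5% of copies
bound. Replicate peak sets of one TF are tested separately, then
averaged per (TF, family) with the minimum q driving selection.

PWM scanning is FIMO-style but not bit-compatible: score =
sum log2(p_motif/p_background) over the window, both strands, zero
probabilities smoothed to 1e-4, windows containing non-ACGT skipped and
counted. The default hit threshold is a log2-odds of 6.0, configurable.
The DHS+/DHS- contrast takes DHS+ as elements open in >= 5 samples and
DHS- as elements open in none, excluding intermediates (the conservative
reading), Fisher per motif with BH across motifs.

## CRISPRi evaluation

dCas9 peaks are classified by family precedence (first listed target
family wins on dual overlap — published counts are disjoint without a
stated rule); class counts always partition the peak set. Signal ratios
use windows of +-500 bp around the integer peak-centre
(`floor((start+end)/2)`), truncated at chromosome ends and flagged, with
`log2((sg+c)/(ctrl+c))`, pseudocount c = 1.0. Coverage tracks are read
from bedGraph and summed per base; normalisation is consumed, not
recomputed. Guide target prediction declares a copy recognised when any
protospacer matches either strand within the mismatch budget (Hamming
distance over sliding windows; ambiguity codes count as mismatches);
PAM checking is off by default for dCas9-KRAB, available via `pam=`.

## Synthetic data: what it emulates

Defaults: 2 chromosomes x 1 Mb with 5% excluded in blocks; five LTR
families (100-300 copies, 300-500 bp, 8-12% divergence from a family
consensus by i.i.d. substitution — no indels, keeping planted motif
offsets exact); 30 disease samples, 10 differentiated, 3 cell lines;
background peaks at 70 per mappable Mb (150 bp).

Planted structure: (i) one enriched family whose copies carry a DNase
peak at a fixed internal offset with probability 0.3 per disease/cell
line sample (0.02 in differentiated), but only for the ~50% of copies
marked activatable — copy-level heterogeneity without which a dense toy
genome leaves no permanently closed copies and the DHS- class is empty;
these defaults land the recovered enrichment near 3.5-fold. (ii) A
10-sample mutation subgroup sharing activity draws with mixing weight
0.6, planting inter-sample correlation. (iii) Three chromatin classes
(disease-active, constitutive, repressed) with distinct mark overlap
probabilities. (iv) Ten enhancer-gene links: the linked gene gains
+3 log2 exactly in samples where its element is active (noise sigma
0.5, baseline N(2,1)). (v) Two-exon transcripts starting inside
activatable copies of the enriched family when active. (vi) Two 20-nt
guides lifted from the enriched-family consensus, <= 2 mismatches; a
related family's consensus is derived from the enriched one at 12%
divergence so the guides cross-react, as with real LTR subfamilies.
dCas9 peaks sit on recognised copies plus 30 uniform off-target peaks;
guide-condition coverage is multiplied by 0.5 (H3K27ac) and 3.0
(H3K9me3) in +-500 bp windows at on-target sites. A self-audit
re-derives every manifest entry from the emitted files by brute force.

What it does not emulate: read-level noise, peak-calling artefacts,
fragment-size effects, indels/structural variation within elements,
linked selection between families, realistic genome size or gene
density. Passing recovery tests shows the statistics behave correctly
under the stated generative assumptions — not that real consortium-scale
data would yield any particular family list.

## Problem sizes used in validation

Null calibration uses 200 simulated samples x 100 shuffles x 5 families;
parameter recovery uses 100 seeded runs (family filters), 1,000 planted
and 1,000 unlinked gene-element pairs, 20 clustering seeds and 100
mutation-subgroup runs; oracle equivalence uses >= 1,000 random
instances per primitive. The full default pipeline runs in well under a
minute on one CPU, and the acceptance script in about half a minute.

## Known limitations

- The shuffle null treats peaks as independent; real DHSs cluster, so
  genuine null variance may exceed the permutation variance.
- Fisher-based contrasts are conservative at small counts.
- The mutation comparison detects a shift in median correlation only;
  it is blind to subgroup structure not aligned with the labels.
- K-means assumes roughly spherical clusters on overlap fractions;
  the elbow table is a diagnostic, not an automatic model choice.
- MEME parsing is via Biopython's minimal-format reader; motifs written
  by this package use a large `nsites` so probabilities round-trip.
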