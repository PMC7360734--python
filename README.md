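# ervreg

Discovery and characterisation of transposable-element (TE) families with
disease-associated regulatory chromatin, built around the example of
endogenous retrovirus (ERV) enhancers in acute myeloid leukaemia (AML).

Roughly half of the human genome is repeat-derived, and the long terminal
repeats (LTRs) of ERVs carry intrinsic promoter/enhancer sequence. In
cancers with relaxed chromatin, individual LTR copies can be co-opted as
enhancers of nearby oncogenes. `ervreg` implements the computational
workflow for finding such families and characterising their activity from
standard epigenomic inputs (peak calls, repeat annotation, transcript
models, normalised expression, coverage tracks), plus a fully synthetic
data generator with a ground-truth manifest for validating every step.

## What it computes

**Repeat-family enrichment (the core statistic).** For one sample with
peak set $D$ (e.g. DNase-seq DHSs) and a repeat family $F$, the observed
statistic is the number of peaks overlapping any copy of $F$ (>= 1 bp,
half-open coordinates). The null is built by re-placing every peak,
length preserved, uniformly at random into the mappable genome (excluded
regions avoided entirely) $N$ times (default $N=1000$). With $o$ the
observed count and $n_1,\dots,n_N$ the null counts:

$$\text{fold} = \frac{o}{\bar n}, \qquad
p = \min\!\Big(1,\; 2\min\big(\tfrac{1+\#\{n_i \ge o\}}{N+1},\;
\tfrac{1+\#\{n_i \le o\}}{N+1}\big)\Big)$$

A family is *enriched in a sample* when `p < 0.05`, `fold > 2`, and more
than 20 distinct copies are overlapped; a family is *selected* overall
when it is enriched in at least one cell line and in strictly more than
10% of disease samples.

**Downstream characterisation.**

- `heterogeneity` — binary element x sample overlap matrix, inter-sample
  correlation (phi/Jaccard), and a label-permutation test of whether
  samples sharing a mutation are better inter-correlated.
- `chromatin` — per-element histone-mark overlap fractions
  (H3K27ac/H3K4me1/H3K4me3/H3K9me3 x disease/differentiated), k-means
  clustering, and a rule-based state call (promoter-like, active/primed
  enhancer, heterochromatic, unmarked).
- `promoters` — TSSs of multi-exon transcripts falling inside elements;
  elements active in >= 2 disease samples and no differentiated sample.
- `genes` — genes within 50 kb of an element; expression contrast between
  samples with and without a DHS at the element, flagged at > 4-fold
  (2 log2 units) with positive DHS+ mean.
- `motifs` — TF peak enrichment per family against shuffled-element
  controls (Fisher exact + Benjamini-Hochberg, selected at q < 0.05 and
  >= 5% coverage), log2-odds PWM scanning of both strands, and DHS+/DHS-
  motif frequency contrasts.
- `crispri` — dCas9 peak classification (on-target family precedence vs
  off-target), +-500 bp histone signal log2 ratios between guide and
  control conditions, proximal genes, and Hamming-distance guide target
  prediction over element sequences.
- `synthetic` — seed-deterministic toy dataset (genome, repeats,
  sequences, peaks, transcripts, expression, coverage, mutations) with
  every planted effect recorded in a JSON truth manifest.

## Worked example

```python
from ervreg.synthetic import SyntheticConfig, generate
from ervreg.enrichment import family_dhs_enrichment, results_to_frame

ds = generate(SyntheticConfig(seed=1))          # 2 Mb genome, 5 families
res = family_dhs_enrichment(ds.dnase["AML01"], ds.repeats, ds.genome,
                            n_shuffles=1000, seed=0)
print(results_to_frame(res)[["family", "observed", "elements_hit",
                             "null_mean", "fold", "p", "passes"]]
      .round(3).to_string(index=False))
```

```
family  observed  elements_hit  null_mean  fold     p  passes
LTR12C        22            21     15.381 1.430 0.156   False
LTR13A         1             1      4.184 0.239 0.160   False
  LTR2         4             4      7.010 0.571 0.332   False
 LTR2B        56            54     15.499 3.613 0.002    True
 LTR5B        10            10     11.498 0.870 0.797   False
```

The generator planted elevated open chromatin at LTR2B copies in disease
samples: 56 of this sample's peaks overlap LTR2B copies where ~15.5 are
expected under random placement (3.6-fold, empirical p = 0.002, 54
distinct copies hit), so LTR2B passes all three filters; the four
unplanted families do not.

The same analysis runs end to end from the command line:

```bash
ervreg run --seed 1 --data-dir out/data --out-dir out/run
```

which writes per-stage TSV/JSON reports (enrichment table, selected
families, correlation and mutation tables, state calls, promoter calls,
expression contrasts, TF/motif tables, CRISPRi ratios) plus a provenance
block. Identical seeds reproduce identical outputs byte for byte.

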