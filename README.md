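# hicarch

Comparative Hi-C chromatin-architecture analysis for two-condition designs:
matrix balancing, A/B compartment calling, TAD-like domain and chromatin-loop
detection, differential-contact testing, and enrichment of gene sets in
changed architecture regions — with a ground-truth synthetic generator for
validation.

## The problem

Hi-C measures genome-wide contact frequencies between genomic bins.
Comparing two conditions (e.g. two tissues, or two developmental states of
an inflorescence bud) asks three nested questions: which megabase-scale
**A/B compartments** flipped (sign changes of the leading eigenvector of the
O/E correlation matrix), which **TAD-like domains** appeared, vanished, or
shifted their boundaries, and which **focal loops and pixel-level contacts**
changed — and whether differentially expressed genes (DEGs) concentrate in
those changed regions, which is the evidence that chromatin reorganisation
participates in the transcriptional change.

The statistics at the core:

- **Balancing (ICE):** biases `b_i` such that `balanced[i,j] = raw[i,j]/(b_i b_j)`
  has equal marginals over unmasked bins.
- **Compartments:** sign of PC1 of the Pearson correlation matrix of O/E
  columns, oriented so A (positive) is the gene-richer compartment.
- **Domains:** insulation-score minima (diamond statistic, log2 to a running
  mean) or arrowhead corner scores; flat segmentation.
- **Loops:** Poisson test of each pixel's raw count against a donut-local
  expectation, BH per distance stratum; validated by APA
  (centre over lower-left corner of the aggregate O/E submatrix).
- **Differential contacts:** per-pixel `M = log2((v2+1)/(v1+1))` vs distance
  `D`, loess joint normalisation, variance-whitened robust Z per distance
  stratum, BH across pixels.
- **Enrichment:** upper-tail hypergeometric probability
  `P(X ≥ k)` for `k` hits among `n` draws from a population `N` with `K`
  class members (the R `phyper` convention), computed in log space.
- **Group contrasts:** Welch's two-sample t-test (unequal variances).

## Worked example

```python
import hicarch as h

cfg = h.default_config(seed=1)                 # two 4 Mb chromosomes, 10 kb bins
m1, m2, genes, degs, truth = h.simulate_pair(cfg)

b1, b2 = h.balance(m1), h.balance(m2)
oe1 = h.oe_transform(b1, h.expected_profile(b1))
oe2 = h.oe_transform(b2, h.expected_profile(b2))

t1 = h.call_compartments(oe1, genes)
t2 = h.call_compartments(oe2, genes)
comp = h.compare_compartments(t1, t2)
print(comp.summary)
# {'A->B': 103, 'B->A': 108, 'NA': 4, 'common-A': 294, 'common-B': 291}

d1, d2 = h.call_domains(b1), h.call_domains(b2)
print(h.domain_stats(d1))
# {'count': 24, 'median_length': 85000.0, 'coverage': 0.26125}

table = h.loess_joint_normalize(h.md_table(m1, m2))
dc = h.detect_differential(table, fdr=0.05)
classes = h.RegionClassMap.from_comparisons(comp, h.compare_domains(d1, d2))
enr = h.enrich_genes_in_classes(h.filter_degs(degs), genes, classes)
print(enr[enr["class"] == "changed"][["class", "k", "n", "fold", "pvalue"]])
#      class    k    n      fold        pvalue
# 0  changed  106  200  1.988978  5.094865e-17
```

Reading the output: 211 of the 800 bins changed compartment (the two flipped
1 Mb blocks, recovered almost exactly); 24 domains of median 85 kb cover 26%
of the genome, closely matching the programmed layout (24 domains, median
90 kb); and the 200 DEGs are strongly
enriched in changed-compartment bins (fold ≈ 2, hypergeometric p ≈ 5e-17),
exactly the integration signal the pipeline is built to detect.

The same run is available as a CLI over a working directory:

```bash
hicarch simulate --out run/ --seed 1
hicarch balance --dir run/
hicarch compartments --dir run/
hicarch domains --dir run/
hicarch loops --dir run/
hicarch diffhic --dir run/
hicarch enrich --dir run/
hicarch report --dir run/        # report.tsv + report.html
```

All artifacts are plain text (TSV / BED / BEDPE / bedGraph) and
byte-reproducible from config + seed.

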