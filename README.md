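# chillnet

Chilling-injury scoring and weighted gene coexpression network analysis for
cotyledon cold-stress transcriptomes.

Cotton (and other chilling-sensitive crops) suffer cotyledon necrosis when
seedlings are exposed to low temperature. Experiments that contrast a
cold-tolerant and a cold-sensitive variety typically combine (i) an ordinal
**chilling-injury (CI) index** scored on seedling cohorts, (ii) bulk RNA-seq
of cotyledons across a stress time course, (iii) **weighted gene coexpression
network analysis (WGCNA)** to find modules of co-varying genes tied to
particular stages or physiological traits, (iv) **hub-gene mining** inside
stage-specific modules, and (v) qRT-PCR validation. `chillnet` implements
that whole analysis as a tested, reusable Python pipeline, together with a
synthetic-data generator that plants known modules, hubs, trait couplings and
enriched terms — so every stage can be verified by parameter recovery without
any sequencing data.

## The statistics at the core

* **CI index** — seedlings are graded 0–7 by necrotic-area fraction; a
  variety's index is `CI = 100 · Σᵢ i·Sᵢ / (8N)` where `Sᵢ` counts seedlings
  at grade `i`. CI lies in [0, 87.5] on the percent scale; lower is more
  tolerant.
* **DE gate** — genes pass when BH-adjusted FDR < 0.05 **and** linear fold
  change ≥ 2 (t-test on log2(FPKM+1); pooled-variance Student t by default).
* **Coexpression network** — unsigned soft-thresholded adjacency
  `A = |cor|^β` (β = 12), topological overlap
  `TOM_ij = (ℓ_ij + A_ij)/(min(k_i,k_j) + 1 − A_ij)`, average-linkage
  clustering of `1 − TOM` with a deterministic height-scan cut
  (minModuleSize = 50) and eigengene merging at dissimilarity < 0.75.
* **Module eigengene** — first principal component of the standardized module
  expression; **kME** is each gene's correlation with it; module–sample and
  module–trait relations are Pearson `r` with two-sided Student-t p at
  df = n − 2.
* **Hubs** — genes with kME > 0.8 and stage specificity score SSC > 0.5 at
  the module's preponderant stage; export networks keep the top-100 hubs by
  stage Z-score connected by TOM edges with weight > 0.45.
* **Enrichment** — upper-tail hypergeometric (= one-sided Fisher exact) per
  term with BH q-values.
* **qPCR** — `2^−ΔΔCt` relative quantification and Pearson/slope concordance
  of paired log2 fold changes against RNA-seq.

## Worked example

```python
import chillnet as cn

cfg = cn.SimConfig(seed=1)                      # 18 samples, 5 planted modules
fpkm, design, truth = cn.generate_expression(cfg)

filt = cn.filter_expressed(fpkm)                # max FPKM >= 1
union, _ = cn.deg_union(filt.kept, design)      # DEGs over all stage pairs
res = cn.CoexpressionNetwork(filt.kept.loc[sorted(union)], design).fit()
print(res.summary())
```

```
    module  n_genes  variance_explained preponderant_stage
        M1       56            0.865687              G1.T3
        M2       56            0.862086              G2.T3
        M3       55            0.862210             G1.T24
        M4       54            0.860972              G1.T0
        M5       50            0.862415              G2.T0
unassigned       26                 NaN
```

Five modules are detected, each peaking at its planted stage and explaining
~86% of its members' variance. The module–sample correlation report shows
each module tightly bound to one stage, e.g. M1 vs its peak stage
`r = 0.998, p = 5.2e-21` (n = 18); `cn.module_recovery_ari(truth,
res.partition.labels)` gives 0.88 against the planted partition. Scoring the
synthetic grading cohorts:

```python
for cohort in cn.generate_grades(cfg):
    print(cohort.variety, cn.ci_index(cohort).ci)
# tolerant 4.5625
# sensitive 42.6875
```

— the tolerant variety's CI index is an order of magnitude below the
sensitive one, the contrast the index is designed to quantify.

A CLI mirrors the library: `chillnet simulate`, `ci`, `filter`, `degs`,
`wgcna`, `hubs`, `enrich`, `qpcr` and `run-all`; see `chillnet --help`.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults and
units, what the synthetic generator does and does not emulate, numerical
choices, and known limitations.
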