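# Methods

## Scope and data model

`chillnet` analyses a genes × samples matrix of nonnegative FPKM-scale
abundances under a full-factorial design of genotype × timepoint ×
replicate. A *stage* is one genotype × timepoint cell; the default design
has 2 genotypes × 3 timepoints (0, 3, 24 h of cold stress) × 3 replicates =
18 samples and 6 stages. Everything upstream of the matrix — read QC,
alignment, FPKM estimation — is out of scope; the matrix, design sheet,
trait table, annotation and grade counts are the pipeline's inputs.

## Chilling-injury scoring

Cotyledons are graded 0–6 from the necrotic-area fraction X (grade 1 is a
colour symptom, "yellowish", and therefore an explicit flag, not an area
bin); whole seedlings are graded 0–7 from the fraction Y. The published
seedling bins leave Y = 1/16 unassigned; we close every such gap
left-inclusively, so Y = 1/16 → grade 2. The cohort index is
CI = 100·Σ i·Sᵢ/(8N), computed in exact rational arithmetic and converted
to float only at the end, giving a bit-stable result in [0, 87.5] on the
percent scale. (The source grading protocol describes the index as ranging
"from 0 to 1" while reporting percentages; the formula's true maximum is
87.5 and we follow the formula and the percent scale.)

## Expression filtering and the DE gate

Genes are *expressed* when their maximum FPKM across samples is ≥ 1
(inclusive boundary) and *detected* when > 0. Per-stage expressed sets use
the replicate mean against the same threshold. Sample correlation is plain
Pearson on the FPKM columns; zero-variance samples yield flagged missing
values rather than an exception, because degenerate synthetic inputs must
not abort a run. The display transform for heatmaps is log10(FPKM + 0.01).

Differential expression between two stages is a two-sided t-test on
log2(FPKM + 1) with Benjamini–Hochberg adjustment, gated at FDR < 0.05 and
linear fold change ≥ 2 (FC = (mean_b + c)/(mean_a + c), c = 0.01, i.e.
|log2FC| ≥ 1). The gate is the contract; the statistic is pluggable. The
default statistic is the **pooled-variance Student t**: with three
replicates per group the Welch–Satterthwaite degrees of freedom collapse to
≈ 2 and the unpooled test loses most of its power (measured mean recall
0.69 versus 0.985 for the pooled test on planted 4-fold changes at noise
sd 0.2), while the pooled test keeps the null clean (mean discoveries
≈ 0.1 per 2000 null genes under BH). `variant="welch"` restores the
unpooled test. Negative-binomial count modelling and dispersion shrinkage
are deliberately not reimplemented.

The coexpression input is the union of DEGs over all pairwise stage
comparisons — a construction rule for the gene universe, not a count
target.

## Coexpression network

The network is built on log2(FPKM + 1) (configurable), since Pearson
correlation on the raw FPKM scale is dominated by the right tail of the
lognormal-like abundance distribution. Defaults follow the classical WGCNA
parameterisation: unsigned adjacency |cor|^β with β = 12 (signed variant
available), standard unsigned topological overlap, minimum module size 50,
eigengene merge cut 0.75.

Dynamic tree cut is replaced by a deterministic **height scan**: every
unique merge height of the average-linkage tree on 1 − TOM is tried, and
the height maximizing the number of clusters of size ≥ minModuleSize wins
(ties → lowest height). Clusters below the floor become "unassigned". This
substitute is reproducible, has no tuning parameters beyond the size floor,
and recovers planted structure; it is not expected to replicate any
particular published module count.

The module eigengene is the first right singular vector of the
standardized member profiles — unit Euclidean norm, sign oriented so it is
never anticorrelated with the mean standardized member profile; variance
explained is s₁²/Σs². Modules merge when their eigengenes cluster at
dissimilarity strictly below the cut (boundary exactly at the cut does
*not* merge); merging repeats to a fixpoint and eigengenes are recomputed.
kME is the gene-to-eigengene Pearson correlation. Module–sample correlation
follows standard practice: the eigengene against the one-hot indicator of
each stage's samples; module–trait correlation uses the trait vector
directly. p-values are two-sided Student-t transforms with df = n − 2; at
n = 18 this reproduces the analytic values r = 0.95 → 1.7 × 10⁻⁹ and
r = 0.86 → 4.7 × 10⁻⁶ (2 × 10⁻⁹ and 5 × 10⁻⁶ at one significant figure).

## Hub mining

Stage summaries are FPKM-scale replicate means. The Z-score normalizes each
stage's mean vector over the gene universe (sample sd, ddof 1); the
universe defaults to the full network input set, since a module-local
normalization is equally defensible — it is a configuration choice, not a
derived fact. SSC is the expression share m_{g,s}/Σ_{s'} m_{g,s'} across
the six stages, so rows sum to 1 and SSC → 1 means one-stage expression. A
module's preponderant stage is where its eigengene's stage mean peaks. A
gene is a hub iff kME > 0.8 and SSC at the preponderant stage > 0.5, both
strict. Export networks keep the top-100 hubs by Z-score at the
preponderant stage and every TOM edge with weight strictly > 0.45; node
degree is the incident edge count.

## Enrichment

Upper-tail hypergeometric p per term (identical to the one-sided Fisher
exact test), computed via the scipy survival function, with BH q-values
reported alongside raw p. The default universe is every gene carrying at
least one term; an explicit universe (e.g. all expressed genes) can be
passed. An optional parent-prune drops a term whose annotated ancestor has
a smaller p — a light convenience, not a semantic-similarity reduction.

## qPCR

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the mean ΔCt of
the control condition's replicates (the mean baseline is a choice; a
per-replicate pairing would be equally valid but requires matched
replicates); RQ = 2^−ΔΔCt, so the geometric mean of control RQs is exactly
1. Platform concordance is Pearson r (Student-t p, df = n − 2) and
least-squares slope on paired log2 fold changes.

## Synthetic generator

The generator's defaults *are* the study conditions: 18 samples in 6
stages, five planted modules of 60 genes among 500, hub fraction 0.1, hub
loading 0.95, replicate noise sd 0.3, and grading cohorts of 200.

The latent scale is **log2** — the field's standard fold-change scale — so
noise sd 0.3 corresponds to ≈ 23% CV between biological replicates, a
realistic figure for RNA-seq. Each module's latent stage profile is the
standardized one-hot indicator of its assigned stage scaled by a log2-fold
amplitude (default 1.1, i.e. a hub's peak stage sits ≈ 2.8 log2-fold ≈
7-fold above its off-peak level). A module gene's log2 expression is
μ_g + λ_g·e_m + ε with μ_g ~ N(3, 1), λ = 0.95 for hubs and
N(0.57, 0.04) otherwise, ε ~ N(0, 0.3); background genes are stage-flat
μ_g + ε with μ_g ~ N(2, 2), so a realistic minority falls below the
expressed filter. The amplitude and loading spread were fixed by a
separation analysis: SSC at the peak stage crosses 0.5 near loading
λ* = ln5/(amplitude·ln2·2.683) ≈ 0.79, roughly midway between the hub
loading (0.95) and the non-hub mean (0.57), with ≈ 2.5–3 σ of margin on
each side against the replicate-noise floor — which is what makes the
planted hubs recoverable at the default kME/SSC thresholds by design
rather than by luck.

Traits are coefficient × (unit-sd latent profile) + Gaussian noise; grade
cohorts draw each seedling's grade from Binomial(7, 1 − θ), a
binomial-thinned multinomial that is monotone in θ with degenerate ends
(θ = 1 → all grade 0; θ = 0 → all grade 7, CI = 87.5). The default variety
parameters θ = 0.949 and 0.507 put the expected CI indices at
87.5(1 − θ) ≈ 4.5% and 43% — the contrast between a tolerant and a
sensitive cultivar. Annotation terms hit background genes at rate 0.05 per
(gene, term) pair; planted terms hit their target module at 20× that rate.

What the generator does **not** emulate: count noise (no NB sampling;
lognormal only), gene–gene correlation inside the background, library-size
or length biases, batch effects, dropout, and any sequence-level artifact.
Passing recovery tests therefore demonstrates correctness of the analysis
machinery under the assumed signal model, not robustness to every
pathology of real RNA-seq.

## Numerical choices and degenerate inputs

Exact rational arithmetic for CI; float comparisons at documented
tolerances elsewhere (TOM vs brute force 1e-12, eigengene vs independent
PCA 1e-9). Zero-variance genes are excluded from the network with a logged
manifest; zero-variance samples flag missing correlations; constant genes
drop from eigengenes with a warning and get missing kME; all-zero genes
get missing SSC; a constant stage makes the Z-score an error (zero
dispersion is unrecoverable). Merge and hub thresholds are strict
inequalities by contract. fcluster's ≤-height semantics are converted to
the strict-< merge rule by stepping one ulp below the cut height.

## Problem sizes

The test suite and the acceptance script run the generator at its default
500-gene scale (TOM of the ≈ 300-gene DEG union), 40–100 replicate
simulations for the DE-gate and calibration checks, and 200 null
simulations for the enrichment PIT — sizes chosen so the whole suite
completes in seconds while every planted effect is still comfortably
detectable.

## Known limitations

* The height-scan tree cut finds compact, well-separated modules; nested
  or strongly overlapping modules (where dynamic tree cut's adaptive
  branch logic helps) may be split or absorbed differently.
* When the DE gate prunes a planted 60-gene module below the 50-gene
  module-size floor, the module drops out entirely (observed at one seed
  with the Welch variant's narrower union); module sizes near the floor
  are intrinsically fragile.
* The hypergeometric p is discrete and conservative at small term sizes;
  calibration checks must use the randomized probability-integral
  transform, and users comparing p across terms of very different sizes
  should be aware of the granularity.
* The 2^−ΔΔCt model assumes perfect (2-fold per cycle) amplification
  efficiency for target and reference alike.
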