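# Methods

This note records the models, estimators, numerical conventions and design
choices behind each stage of the pipeline, and what the synthetic-data
generator does and does not emulate.

## Synthetic panel generator

**Genotypes.** Accessions are organized into subpopulations (default
70/59/59 = 188, labelled SCC, TC, PGC — spray cut, traditional, and
potted-and-groundcover germplasm classes). Each SNP draws an ancestral
frequency p ~ U(0.05, 0.95); subpopulation frequencies follow the
Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `base_fst`
(default 0.05, in the range of the subgroup differentiation reported for
cultivated chrysanthemum panels). Dosages are binomial(2, q) per accession;
missing calls are missing-completely-at-random at rate 0.02. Chrysanthemum
is polyploid, but the genotype calls are modelled as diploid dosages
{0, 1, 2}, matching the representation of the GBS SNP panel this emulates;
no polyploid genotype likelihoods are attempted. Default genome: 3
chromosomes × 1 Mb at 2 000 SNPs/Mb — a desk-scale stand-in for a 27-
chromosome, multi-Gb genome; window statistics are per-bp, so conclusions
about the scan's behaviour transfer, while absolute π values do not (SNP
density on the real genome is ~100× lower).

**Planted sweeps.** Inside a sweep interval the improved class's allele
frequencies are first shifted by Δp (default 0.6) toward the nearer
boundary, then rescaled so expected heterozygosity 2q(1−q) drops by the
`diversity_fold` factor (default 5×), staying on the same side of 0.5. One
100-kb sweep per chromosome, aligned to the 10-kb window grid, is the
default planting.

**Relatedness.** With `family_size = k > 0`, accessions within a
subpopulation form full-sib families (two binomial founders, k−2 Mendelian
offspring). This supplies the within-group kinship that ancestry components
cannot absorb — the regime in which mixed-model association is expected to
out-perform a structure-covariate GLM, and typical of germplasm collections
with shared breeding parents. The default is unrelated accessions.

**Phenotypes.** Trait value = genetic value + year main effect (SD 0.4) +
genotype-by-year deviation (variance V_gE) + replicate error (variance V_e),
on a standardized scale mapped affinely onto each trait's measurement scale
(means and SDs chosen to match a two-year rooting assay of a diverse panel;
e.g. TL 38 ± 20 cm, AD 0.72 ± 0.16 mm). The genetic value combines three
latent factors — length/area, diameter, root number, echoing the principal-
component structure of rooting traits (AD loads negatively on the length
factor) — plus any planted per-SNP causal effects, empirically rescaled to
variance V_g. Given a target H², components are set to
V_g : V_gE : V_e with V_gE/l + V_e/(r·l) split evenly and the total
normalized to 1, so the floor at zero (trait values are non-negative)
censors only the extreme lower tail (~2–4 % of observations; the residual
bias this leaves in recovered H² is well inside the recovery tolerance).
Counts (NT, NR) are rounded, NR ≥ 1, and AL is recomputed as TL/NR so the
derived-trait identity holds exactly. Per-trait default H² targets follow
the published range for rooting traits (0.37–0.68).

**Expression.** Genes × samples counts are gamma-Poisson (NB shape 20)
around 2^(base + 1.4·z + lfc-shift), base ~ N(7, 1.2) on the log2 scale.
Module genes share a latent factor with loading λ and balanced signs
(activated and repressed halves): balanced signs mean a module has no net
library-size footprint, so FPKM/CPM normalization does not erode the planted
within-module correlation (≈ λ² in magnitude) at desk scale — and mixed-sign
regulation is how real modules look. Planted fold changes are added on the
exact log2 scale with direction following each gene's loading sign.
Background genes get heterogeneous amplitudes (U(0.15, 0.85) of the module
amplitude), so variability filters rank module genes highly, as with real
co-regulated programs. Sample traits can be linked to module factors at a
chosen correlation. Not emulated: gene length/GC biases, isoform structure,
batch effects, and the 40 000-gene scale of a full transcriptome.

All generators are pure functions of (configuration, seed); per-stage child
seeds derive from the master seed via numpy's SeedSequence.

## Phenotype scoring

* **Descriptive statistics** are computed on per-accession means within
  year; SD is the sample (n−1) estimate, CV = 100·SD/mean, kurtosis is
  excess kurtosis. Correlations are Pearson with two-sided p-values.
* **BLUEs** treat genotype as fixed and year as random with replicate error
  residual: the GLS solution under V = σ²_year·ZZ' + σ²_e·I, with the two
  variances estimated by method of moments (residual MS after a
  genotype+year fixed fit; year MS). In a balanced complete design this
  reduces exactly to the genotype mean. Missing cells are handled by the
  fitted model; an accession absent for a trait is dropped with a warning.
* **Variance components** come from the two-way ANOVA expected mean
  squares: V_e = MS_err, V_gE = (MS_GxE − MS_err)/r, V_g = (MS_G −
  MS_GxE)/(r·l); negative moment estimates truncate to zero and are
  flagged. H² uses the entry-mean formula above; with one environment V_gE
  is inestimable and H² = V_g/(V_g + V_e/r). ANOVA method-of-moments was
  chosen over REML for determinism and closed form; the synthetic designs
  are balanced, where the two coincide in expectation.
* **Trait PCA** is on the correlation matrix (traits have heterogeneous
  units; required for the score's scale invariance), with a deterministic
  sign convention: the largest-magnitude loading of each component is
  positive.
* **Composite score.** CI_j is the accession's score on retained component
  j (the standard membership-function workflow), U_j its min–max rescaling
  over the panel, W_j the component's share of the retained variance, and
  D = Σ U_j·W_j. Retention defaults to eigenvalue > 1 with
  cumulative-variance and fixed-count overrides. A retained component with
  zero score range is dropped with a warning and the weights renormalized.
  D is invariant to positive affine rescaling of any trait and lies in
  [0, 1] by construction.
* **Group comparison** uses Welch's two-sided t-test with significance
  stars at 0.05/0.01/0.001; two zero-variance groups with equal means give
  p = 1.

## Sweep scan

Per-site π is the unbiased mean pairwise difference 2·n_ref·n_alt/(n(n−1))
over non-missing alleles; the window value divides the site sum by the full
window span in bp (monomorphic positions contribute zero implicitly —
recorded because conventions differ). F_ST is Weir–Cockerham (1984) with
two populations, observed heterozygosity taken from dosage-1 genotypes, and
the window-level ratio-of-sums ("weighted") estimator Σa/Σ(a+b+c); negative
values are retained so quantiles are honest. Windows default to 100 kb with
10-kb steps, truncating at chromosome ends. The π-ratio excludes windows
with a zero denominator or fewer than `min_snps` (default 10) usable sites
in either group — pseudocounts would let near-empty windows dominate the
upper tail. Thresholds are empirical quantiles with numpy's linear
interpolation between order statistics; a window is called iff it reaches
both thresholds; selected windows sharing ≥ 1 bp or exactly abutting merge.
By construction at most ⌈(1−q)·windows⌉ windows are selected per statistic;
each merged interval can extend at most (window − step) bp beyond its
selected steps, which bounds the flagged genome fraction at the quantile
budget plus that merge slack. Coordinates are 1-based inclusive internally;
BED export converts to 0-based half-open. The scan contrasts germplasm
classes by label (TC vs SCC), not inferred clusters.

Genome-wide subgroup π divides the total site sum by total genome length;
pairwise subgroup F_ST is the ratio of sums over all sites.

## Population structure

The kinship matrix is the VanRaden genomic relationship matrix: per-site
mean imputation of missing dosages, centering at 2p and scaling by
√(2p(1−p)) (monomorphic sites skipped), averaged over SNPs — its mean
diagonal is ≈ 1 under random mating. PCs are eigenvectors of K scaled by
√eigenvalue; the default ancestry covariate matrix Q is the top
(subpopulations − 1) components. Neighbor joining follows Saitou–Nei with
the default distance 1 − IBS proportion; Q-matrix ties break at the
smallest index pair (row-major argmin), negative branch lengths clamp to
zero with the deficit moved to the sister branch, and the final three nodes
join by the three-point formulas. The implementation is cross-checked
against an independent NJ implementation in the test suite.

## GWAS

The GLM is OLS of the trait on [intercept, Q, dosage] with a two-sided
t-test on the dosage coefficient; covariates are projected out once via QR,
making the per-SNP scans a vectorized simple regression. Missing dosages
are mean-imputed per SNP. The MLM uses the EMMAX/P3D approximation: the
variance ratio δ = σ²_e/σ²_g is estimated once on the null model by REML
over the kinship eigendecomposition (coarse log-grid on δ ∈ [1e−5, 1e5]
refined by bounded scalar minimization — deterministic and derivative-
free), then every SNP is tested by GLS under the fixed fitted covariance.
With K = I the MLM reduces to the GLM (verified to 1e−6). SNPs collinear
with the covariates are reported inestimable (missing p) rather than
dropped. Genomic inflation λ is the median association χ² over its null
median (0.4549).

Significance uses Bonferroni at 1/Me only, as is standard with an
effective-marker count; no FDR across SNPs. Me can be supplied (the
published panel value is 292 493, giving p ≤ 3.42e-06, −log10 = 5.47) or
estimated by a simplified per-chromosome eigenvalue rule (Li & Ji-style
f(λ) = I(λ ≥ 1) + (λ − ⌊λ⌋) summed over the SNP-correlation eigenvalues).
The estimator is *not* the GEC algorithm that produced the published value,
and with far fewer samples than SNPs it is rank-limited and conservative —
for that reason the end-to-end pipeline defaults to plain Bonferroni over
the tested SNPs unless Me is supplied, and the estimator is opt-in.

Candidate genes lie within a ±50 kb flank of a significant SNP (inclusive
at exactly the flank; distance zero inside the gene span; strand not
consulted; the relative-position label places the gene with respect to the
SNP coordinate). Genotype-class summaries label dosage classes by ref/alt
allele pairs and report per-class means, germplasm composition and pairwise
Welch tests, excluding classes with fewer than two members.

## Differential expression and co-expression

The DE test is an explicit simplification of a negative-binomial analysis:
log₂FC from group means of CPM with a 0.5 pseudocount, p from a Welch
t-test on log₂(CPM+1), Benjamini–Hochberg adjustment, and the exact
classification thresholds padj ≤ 0.05 and |log₂FC| ≥ 1 (both inclusive).
`classify_de` applies only the classification, preserving fidelity when an
external DE table is available.

The module pipeline runs on log₂(FPKM+1) (FPKM = counts·10⁹/(length·library
size)). The MAD filter keeps the ⌈fraction·G⌉ most variable genes (default
30 %), ties broken by input gene order. The network is unsigned: adjacency
|r|^β with β the smallest integer in 1..20 whose scale-free fit R² reaches
0.85 (10-bin log-log regression of the connectivity distribution, signed by
slope). When no power reaches the floor — the expected outcome when the
true network is a few strong modules rather than scale-free — the fallback
is the conventional sample-size-based unsigned power (10/9/8/7 for
< 20/30/40/more samples) rather than the R²-argmax, which on modular data
drifts to the grid maximum and flattens the topology. Topological overlap
(L + a)/(min k + 1 − a) is clustered by average linkage; the tree is cut
statically at TOM-dissimilarity 0.995 (unrelated genes sit at ≈ 1,
co-expressed blocks well below; the cut is a parameter); clusters under 30
genes are unassigned. Modules whose eigengenes correlate above 0.7 in
absolute value merge iteratively. Eigengenes are unit-variance first PCs of
the standardized module expression, sign-anchored to positive mean
gene–eigengene correlation. GS is the gene–trait correlation, MM the
gene–own-eigengene correlation; hubs require |GS| > 0.2 and |MM| > 0.8
(strict), with each module's GS evaluated against its most-correlated trait
by default (configurable). Dynamic tree cutting and dispersion-shrunk DE
are deliberately out of scope.

## Integration

Overlaps are exact set intersections (pairwise and triple) with sorted,
stable member lists. Enrichment is the upper-tail hypergeometric
P(X ≥ k) per term (over-representation only) with BH across terms and a
q ≤ 0.05 flag. qPCR relative expression averages replicate Ct values before
differencing, ΔCt = Ct_target − Ct_reference, ΔΔCt subtracts the calibrator
sample's ΔCt, relative expression = 2^−ΔΔCt — the calibrator is exactly 1
for every target. No amplification-efficiency correction is applied.

The end-to-end pipeline chains the stages on simulated data, maps simulated
expression genes onto the annotation's gene ids (GWAS candidates first, so
the cross-stage overlap machinery has non-trivial input), and emits a
deterministic JSON summary.

## Problem sizes and validation

The validation suite runs at desk scale, chosen so the full suite completes
in well under a minute of compute per experiment: sweep recovery on 2 × 50
accessions, 3 × 1 Mb chromosomes, ~2 000 SNPs/chromosome over 10 seeds;
heritability recovery on 188 × 2 years × 3 replicates over 20 seeds;
mixed-model calibration on 188 accessions × ~5 000 SNPs (3 subpopulations,
sib families of 5, polygenic h² = 0.6) over 10 seeds; module recovery on
two 50-gene blocks (loading 0.9) plus 100 background genes × 30 samples
over 10 seeds. Medians over seeds are reported throughout to be robust to
individual draws.

## Known limitations

* Diploid dosage coding of a polyploid genome; no genotype likelihoods.
* The ANOVA variance decomposition assumes (near-)balanced designs; badly
  unbalanced trials would warrant REML.
* The Me estimator is rank-limited when accessions ≪ SNPs; supply an
  externally computed Me for real panels.
* The static tree cut is simpler than dynamic hybrid cutting and can
  truncate modules on weakly separated data.
* The DE test is a mean/variance approximation; import a negative-binomial
  table for publication-grade calls.
* Synthetic data are missing-completely-at-random and free of genotyping
  error, batch effects, and linkage disequilibrium beyond subpopulation and
  family structure.
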