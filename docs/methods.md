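# Methods

This note documents the statistical procedures implemented in
`qtlallele`, the assumptions behind them, the synthetic-data generator
that stands in for an undeposited germplasm panel, and the numerical
choices that a reader would otherwise have to recover from the source.

## 1. Membership-index phenotyping (`qtlallele.phenotype`)

The pipeline phenotypes stress tolerance from a replicated two-regime
trial (stress vs non-stress, r replications, both regimes measured for
every accession in every replication). For accession *i* and replication
*k* the relative trait value is the within-replication ratio

    X_ik = value(stress) / value(non-stress),

and the membership index rescales X affinely so that the sensitive-check
group mean maps to 0 and the tolerant-check group mean maps to 1:

    M_ik = (X_ik − X_kS) / (X_kT − X_kS).

The accession's indicator value (MPW for plant weight, MPH for plant
height) is the unweighted mean of M_ik over replications. Values outside
[0, 1] are meaningful — they flag accessions more extreme than the
checks — and are never clipped. The transform is exactly invariant to a
shift or positive rescaling of all X within a replication, which is what
the check anchoring is for: it removes per-replication environment
without modeling it.

Broad-sense heritability is estimated from a one-way random-effects
ANOVA with accession as the factor:

    σ²_g = max(0, (MS_accession − MS_error)/r),   σ²_e = MS_error,
    h² = σ²_g / (σ²_g + σ²_e / r)   (replication-mean basis, clamped to [0, 1]).

For near-balanced data r is replaced by the standard effective group
size n₀ = (N − Σn_i²/N)/(a − 1). A one-way model (rather than the full
split-plot) is deliberate: h² is consumed downstream only as the cap and
the weight for the association model, and the membership transform has
already absorbed the replication main effect up to the noise of the
check means (see §6). Negative variance components are truncated at
zero, the usual method-of-moments practice.

## 2. SNPLDB markers (`qtlallele.snpldb`)

QC keeps SNPs with (missing + heterozygous) call rate ≤ 30% and minor
allele frequency ≥ 1%, then converts surviving heterozygous calls to
missing — the panel is a self-pollinated species collection, so residual
hets are treated as call errors. Missing calls are imputed to the SNP's
major allele, deterministically; with the missingness the generator
produces (a few percent, uniform) model-based haplotype imputation would
change almost nothing, and the imputer's expected accuracy equals the
major-allele frequency by construction, which the tests check.

Haplotype blocks are found with the confidence-interval method. For a
SNP pair, inbred homozygous calls are read directly as haplotypes; D′ is
D/D_max with the usual normalization, and the CI of |D′| comes from the
multinomial likelihood of the 2×2 haplotype table evaluated on a
201-point grid of |D′| ∈ [0, 1] with allele frequencies held at their
observed values. Bounds are the cumulative 5th and 95th percentiles of
the normalized likelihood (one-sided tails, as in the classical
implementation of this method). A pair is *strong LD* when ci_low > 0.70
and ci_high ≥ 0.98, *strong recombination* when ci_high < 0.90. A
candidate interval is one whose outermost pair is strong LD; it is
accepted when ≥ 95% of its informative inner pairs are strong LD, taking
candidates greedily from longest bp span to shortest without overlap.
Pairs farther apart than 200 kb are never examined. All four thresholds
and the span limit are exposed as arguments.

Each accepted block becomes one multi-allele marker whose alleles are
the observed haplotype strings; haplotypes rarer than 1% are merged into
the most similar frequent haplotype (minimum Hamming distance, ties to
the higher-frequency target, then lexicographic) so allele counts stay
bounded and every allele remains an interpretable haplotype rather than
an "other" bucket. SNPs outside blocks are carried as two-allele
markers. Ids follow `<chrom>_BLOCK<k>` (multi-SNP, k counting per
chromosome in genomic order) and `<chrom>_<pos>` (singletons).
Coordinates are 1-based inclusive throughout, matching VCF.

Note one property the tests rely on: with at most three haplotypes in a
block, every internal SNP pair shows at most three gametic classes and
|D′| = 1 exactly, so noiseless blocks are recovered verbatim. Pools of
four or more haplotypes can legitimately contain all four gametes at
some pair, and the CI method is then entitled to split the block — that
is a property of the method, not an implementation artifact.

## 3. Similarity and structure (`qtlallele.similarity`)

The genetic-similarity matrix is the fraction of markers at which two
accessions carry the identical allele — the simplest multi-allele
identity coefficient, with no frequency weighting (a config hook exists
for alternatives). Its top k eigenvectors (default k = 10; capped at
n − 1 with a warning on small panels) enter both association stages as
fixed covariates. The eigendecomposition uses a symmetric solver, sorts
eigenvalues descending, and fixes each vector's sign so its
largest-magnitude entry is positive, making results reproducible across
runs and BLAS builds. One shared basis is used for both indicators.

## 4. Two-stage multi-locus association (`qtlallele.association`)

*Stage 1* fits, for every marker, phenotype ~ intercept + eigenvectors +
marker-as-categorical and tests the marker term with a partial F test
against the covariate-only model. Markers with p ≤ 0.05 are
pre-selected. Alleles with fewer than 3 carriers are folded into the
reference (most frequent) allele; markers with fewer than two testable
alleles are skipped and logged. The phenotype is the accession mean of
the membership index (replication-level fitting would be an alternative;
means were chosen and the choice is explicit in the pipeline).

*Stage 2* is forward-backward stepwise regression over the pre-selected
markers under the multi-locus multi-allele model. At each forward step
the candidate with the smallest partial-F p-value enters if p ≤ 0.01,
ties broken by larger partial R², then genomic order (a determinism
requirement); a candidate whose entry would push the genetic R² — the
model sum of squares beyond the covariates over the total phenotypic sum
of squares — above the trait heritability is passed over. After each
entry, included loci with partial p > 0.01 are eliminated, worst first.
The per-step α of 0.01 is consistent with the smallest reported locus
significance in the reference analysis (−log₁₀p ≈ 2.2) and is
configurable; the heritability cap, not a genome-wide correction, is
what bounds the model, which is the point of the restricted two-stage
design: the selected QTL system can approach but never exceed the
heritability, avoiding both missing and overflowing contribution.

The final refit reports, per locus: a partial (type-III-style) R² =
SS(locus | all other selected loci + covariates)/SS_total — partial
rather than sequential because the reported per-QTL contributions should
not depend on selection order — its −log₁₀p, and per-allele effects in
the unweighted sum-to-zero parameterization (effect of allele a = the
adjusted deviation of allele-a carriers from the locus mean). Covariates
are centered before fitting, so the intercept is the prediction at the
population-mean structure and `intercept + Σ carried-allele effects`
reproduces the model's fitted value exactly — the invariant the
QTL-allele matrix is built on. The share h² − R²_total is reported as
the collective contribution of unmapped minor QTL.

All F tests are computed by projecting candidate columns against an
orthonormal basis (QR) of the current design, which keeps the stepwise
scan O(n·p) per candidate and makes every statistic invariant to
accession order to ~1e-10.

## 5. QTL-allele matrix, differentiation, turnover, crosses

The QTL-allele matrix records, per accession × detected locus, the
carried allele and its estimated effect; row sums plus the intercept
give each accession's predicted indicator value. Subpopulation
differentiation is a Pearson χ² (no continuity correction) on each
locus's allele × subpopulation count table, reported with raw p-values
(decisions at α = 0.05, as in the reference analysis) plus a
Benjamini–Hochberg column for the reader; loci with any expected cell
below 5 are flagged, not dropped. An allele is *excluded* when carried
in the ancestral subpopulation only, *emerged* when carried in the
derived one only; tallies are split by the raw sign of the estimated
effect, with exact zeros counted as neither.

Cross prediction enumerates all n(n−1)/2 unordered parent pairs.
Progenies are homozygous derived lines: at each locus of the union of
the two indicators' loci a progeny inherits parent 1's or parent 2's
allele with probability ½, independently across loci (free
recombination — the matrices carry no linkage map), and loci shared
between indicators are sampled once per progeny so the two trait values
stay genetically consistent. A progeny's value is the trait intercept
plus its summed allele effects, i.e. on the indicator scale, which is
what makes the comparison against observed panel maxima meaningful.
Per-cross summaries are linear-interpolation percentiles (numpy's
default rule, pinned and echoed in outputs because percentile
conventions differ). Two optimality criteria exist — progeny 95th
percentiles exceeding the panel maxima, or exceeding the better parent,
jointly over both indicators — and both are implemented with
`exceeds_population_max` as the default; reports always state which was
used. Ranking is by the weighted average value

    WAV = (h²_MPW · v_MPW + h²_MPH · v_MPH) / (h²_MPW + h²_MPH),

with the indicator heritabilities (defaults 0.813 and 0.760, the
reference panel's values) as weights, displayed to three decimals.
No residual polygenic variation is added to progeny values; they are
QTL-model predictions, not phenotype simulations.

## 6. The synthetic generator (`qtlallele.simulate`)

The generator produces the statistical structure the analysis assumes,
not a population-genetic history. An inbred panel is fully homozygous,
so a genotype column is a haplotype; heterozygosity and missingness
exist only as injectable noise for QC tests. SNPs come in contiguous
blocks; each block has a pool of 2–12 distinct haplotypes (default range
2–6, 5 SNPs per block) with every SNP polymorphic within the pool, and
each subpopulation draws its pool frequencies from a Dirichlet with its
own concentration (defaults 0.5 vs 2.0 — visibly drifted), floored at
`min_hap_freq` (default 0.02) and renormalized. With probability
`private_allele_rate` (default 0.10) per subpopulation per block, one
haplotype is zeroed out of that subpopulation's pool, creating the
private alleles that the turnover analysis is about. Blocks are
independent of each other; singleton SNPs fill out each chromosome.

QTL are drawn among polymorphic blocks; per-allele effects are
N(0, effect_sd) centered to sum to zero within each locus. The
genotype-to-phenotype map is linear: the per-replication stress ratio is
X_ik = g_i + ε_ik with g the summed allele effects plus an intercept
(default 0.55, a typical stress/non-stress ratio) and optional
subpopulation shifts. Non-stress values are a trait baseline times a
lognormal replication effect times lognormal noise; stress = non-stress
× max(X, 0.01). Checks are the accessions with the most extreme mean
standardized genotypic values (5 tolerant, 5 sensitive by default),
which guarantees X_kT > X_kS in every replication in practice.

**Noise calibration.** The naive inversion of the heritability formula,
σ²_e = r·σ²_g·(1 − h²)/h², targets h² on X but systematically
undershoots it on M: the membership transform subtracts the
per-replication sensitive-check mean and divides by the check-mean
difference, so the sampling noise of the check means re-enters every
index value as a shift shared within a replication, which the one-way
ANOVA books as error. To first order the effective error variance on M
is σ²_e(1 + 1/n_T + 1/n_S); the generator therefore deflates σ²_e by
that factor (1.4 with 5 + 5 checks). With this correction the
re-estimated h² lands within ±0.05 of an 0.80 target on average over 20
seeds at n = 400, which is what the calibration test asserts.

**What the generator does not emulate**, hence what passing tests do not
show about real data: no coalescent LD decay (blocks are exactly
rectangular and mutually independent, so block detection on real,
raggedly decaying LD is harder than here); no linkage between QTL; no
genotyping-error structure beyond uniform missing/het injection; and the
two traits' QTL systems are drawn independently, so the synthetic
MPW–MPH correlation is near zero, whereas real stress panels show
moderate positive correlation (0.55 in the reference panel) that likely
reflects shared unmapped background the additive two-system model does
not carry. Recovery rates measured here are therefore upper bounds on
block-detection performance and roughly neutral for the association
machinery, which never sees the block geometry.

## 7. Problem sizes, determinism, I/O

The analysis scripts run a 300-accession, 3000-SNP, 15-QTL panel with
500 progenies per cross — sizes chosen so the whole chain replays in
about two minutes on one core while keeping every stage's statistics
stable; the library defaults keep the reference analysis's 10,000
progenies per cross for real use. At this panel scale the jointly
population-max-transgressive cross set is typically empty (with ~20
detected loci the best accession already stacks most positive alleles),
while tens of thousands of crosses transgress their own parents; the
full 135-locus system of the reference panel is what makes
population-level transgression common there.

Every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds from the master seed via `SeedSequence`, so stages can
be re-run in isolation without disturbing each other. Identical
configurations produce byte-identical outputs. All tables are
tab-separated text with `#`-prefixed header comments carrying the
package version, a hash of the full configuration, and the seed; final
tables are written via write-then-rename so an aborted run leaves no
partial files. Genotypes interchange as VCF (homozygous GT calls,
biallelic sites only — multi-allelic sites are rejected by name) or as a
plain SNP × accession matrix TSV.

## 8. Known limitations

No mixed-model (kinship) association — structure correction is by fixed
eigenvector covariates only, as in the restricted two-stage design; no
epistasis; no multi-trait joint model; no permutation thresholds; no
four-gamete or solid-spine block definitions; no phasing. The stepwise
per-step α is a surrogate for the experiment-wise significance
partitioning of the original method description, which is not
reproducible from the available account; the heritability cap carries
the restriction in either case.
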