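# qtlallele

Detecting the QTL-allele system of a stress-tolerance trait in an inbred
germplasm panel, and using it to design crosses.

The package is written for quantitative geneticists and breeders working
with self-pollinated crop panels (the motivating case is drought
tolerance in a 564-accession Chinese soybean panel phenotyped in a
five-replication stress/non-stress pot trial). It implements the full
chain:

1. **Membership-index phenotyping** — per accession *i* and replication
   *k*, the relative trait X_ik = stress/non-stress is rescaled against
   the check accessions, M_ik = (X_ik − X_kS)/(X_kT − X_kS), giving the
   drought-tolerance indicators MPW (plant weight) and MPH (plant
   height); broad-sense heritability h² = σ²g/(σ²g + σ²e/r) comes from
   the one-way ANOVA.
2. **SNPLDB markers** — SNP QC (missing+het ≤ 30%, MAF ≥ 1%),
   major-allele imputation, confidence-interval LD-block detection on
   |D′| (max span 200 kb), and encoding of each block as one
   multi-allele marker whose alleles are its haplotypes.
3. **Restricted two-stage multi-locus association** — single-locus F
   tests with the top eigenvectors of the SNPLDB similarity matrix as
   structure covariates pre-select markers at p ≤ 0.05; forward-backward
   stepwise regression under the multi-allele model then selects the
   QTL, with total genetic contribution R² capped at h². Per-locus
   partial R² and sum-to-zero allele effects are reported.
4. **QTL-allele matrix** — accession × locus matrix of carried alleles
   and effects; χ² differentiation between subpopulations (landraces vs
   released cultivars) and the alleles excluded from or newly emerged in
   the derived subpopulation.
5. **Optimal-cross prediction** — for every biparental cross, simulated
   homozygous derived-line progenies (free recombination, one parental
   allele per locus), 95th-percentile summaries per indicator, joint
   optimality flags, and ranking by the heritability-weighted average
   WAV = (h²_MPW·v_MPW + h²_MPH·v_MPH)/(h²_MPW + h²_MPH).

Because the motivating panel is not publicly deposited, the package
ships a first-class synthetic-population generator
(`qtlallele.simulate`) that reproduces the statistical structure every
stage assumes — inbred genotypes in LD blocks with 2–12 haplotypes,
drifted subpopulation frequencies with private alleles, additive
multi-allele QTL, and replicated two-regime trials calibrated to a
target heritability — plus transcriptions of the published per-locus QTL
summaries and the top-10 cross table (`qtlallele.reference`) for the
worked-example arithmetic. See `docs/methods.md` for models,
assumptions, and numerical choices.

## Worked example

The `analysis/` scripts replay the whole study on a synthetic panel
(300 accessions, 57% landrace-like / 43% cultivar-like, 3000 SNPs in
five-SNP blocks on 20 chromosomes, 15 QTL per indicator, target
h² = 0.80, seed 2026), writing tables under `results/`:

```bash
python analysis/01_simulate_panel.py
python analysis/02_phenotype_indicators.py
python analysis/03_build_markers.py
python analysis/04_association_scan.py
python analysis/05_allele_matrix.py
python analysis/06_predict_crosses.py
```

Output of a run (about two minutes on one core):

```
MPW: h2 = 0.808 (sigma2_g = 0.1830, sigma2_e = 0.2167, r = 5)
MPH: h2 = 0.826 (sigma2_g = 0.0904, sigma2_e = 0.0950, r = 5)
QC: kept 2999/3000 SNPs (0 failed missing/het, 1 failed MAF); imputed 0.00%
682 LD blocks -> 1187 SNPLDB markers (682 multi-SNP, alleles/block 2~5)
MPW: 85 preselected -> 20 QTL, total R2 = 0.733 (h2 cap 0.808, unmapped 0.075)
MPH: 70 preselected -> 16 QTL, total R2 = 0.695 (h2 cap 0.826, unmapped 0.132)
MPW: 20 loci; 17 differentiated at p<=0.05; 1 alleles excluded (1 neg, 0 pos), 0 emerged in RC
44850 crosses simulated with 500 progenies each; ... 29628 jointly exceed their own parents
  ACC0077 x ACC0195: MPW 2.356, MPH 1.138, WAV 1.741
```

Reading this: the trial noise was calibrated to h² = 0.80 and the ANOVA
re-estimates 0.81/0.83; block detection recovers the five-SNP blocks and
reports 2–5 alleles per block, matching the generator's pools; the
stepwise model explains 73%/70% of phenotypic variance — inside the
heritability cap, with the remainder reported as unmapped minor QTL;
most detected loci are significantly differentiated between the drifted
subpopulations; and the top cross's progeny 95th percentile (MPW 2.356)
transgresses both of its parents, which is the breeding signal the
ranking is designed to surface.

The same pipeline runs from the command line (`qtlallele all --config
cfg.yaml --out run/`, with subcommands `simulate`, `phenotype`,
`blocks`, `gwas`, `matrix`, `diff`, `crosses` for stage-wise use), and
on real inputs by pointing `RunConfig` at a VCF or genotype matrix TSV,
a tidy trial CSV, a check roster, and subpopulation labels.

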