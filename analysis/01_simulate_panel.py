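#!/usr/bin/env python
"""Generate the synthetic study panel.

An inbred soybean-like panel of 300 accessions in two subpopulations
(landrace-like LR at 57%, released-cultivar-like RC at 43%, mirroring the
319:245 split of the reference panel), 3000 SNPs in haplotype blocks of
five SNPs on 20 chromosomes, 15 additive multi-allele QTL per trait, and
a five-replication stress / non-stress pot trial calibrated to an
indicator heritability of 0.80.  Writes the panel (VCF + matrix TSV),
trial CSV, check roster, subpopulation labels, and the ground-truth QTL
effects under results/synthetic/.
"""

from pathlib import Path

import pandas as pd

from qtlallele import io
from qtlallele.simulate import SimConfig, simulate_study

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 2026

config = SimConfig(
    n_accessions=300,
    subpop_proportions=(0.57, 0.43),
    n_chromosomes=20,
    snps_per_chromosome=150,
    n_qtl=15,
    target_h2=0.80,
    seed=SEED,
)


def main() -> None:
    panel, models, trial = simulate_study(config)
    OUT.mkdir(parents=True, exist_ok=True)
    meta = {"seed": SEED}
    io.write_genotypes_vcf(panel.genotypes, OUT / "panel.vcf")
    io.write_genotypes_tsv(panel.genotypes, OUT / "panel.tsv", meta)
    io.write_trial_csv(trial.data, OUT / "trial.csv")
    io.write_checks(trial.tolerant_checks, trial.sensitive_checks,
                    OUT / "checks.tsv")
    panel.subpop.rename("subpop").rename_axis("accession").reset_index().pipe(
        io.write_table, OUT / "subpop.tsv", meta
    )
    truth = []
    for trait, model in models.items():
        for bi, eff in zip(model.qtl_blocks, model.allele_effects):
            block = panel.true_blocks[bi]
            for a, e in enumerate(eff):
                truth.append({
                    "trait": trait, "chrom": block.chrom,
                    "start": block.start, "end": block.end,
                    "allele": a, "effect": e,
                })
    io.write_table(pd.DataFrame(truth), OUT / "truth.tsv", meta)
    print(f"panel: {panel.genotypes.n_snps} SNPs x "
          f"{panel.genotypes.n_accessions} accessions "
          f"({(panel.subpop == 'LR').sum()} LR / "
          f"{(panel.subpop == 'RC').sum()} RC)")
    print(f"trial: {len(trial.data)} records, "
          f"checks: {trial.tolerant_checks} / {trial.sensitive_checks}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
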