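#!/usr/bin/env python
"""Assemble multi-allele SNPLDB markers from the panel genotypes.

QC (missing+het rate <= 30%, MAF >= 1%), major-allele imputation,
confidence-interval LD-block detection (max span 200 kb), and encoding of
blocks as multi-allele haplotype markers with singleton SNPs carried as
two-allele markers.  Writes markers.tsv and marker_codes.tsv under
results/markers/.
"""

from pathlib import Path

from qtlallele import io
from qtlallele.snpldb import (
    build_snpldb_markers,
    find_ld_blocks,
    impute_missing,
    qc_filter_snps,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = io.read_genotypes(ROOT / "synthetic" / "panel.tsv", "matrix_tsv")
    gm, report = qc_filter_snps(gm)
    gm, frac = impute_missing(gm)
    print(f"QC: kept {report['n_kept']}/{report['n_input']} SNPs "
          f"({report['n_removed_missing_het']} failed missing/het, "
          f"{report['n_removed_maf']} failed MAF); imputed {frac:.2%}")
    blocks = find_ld_blocks(gm)
    markers = build_snpldb_markers(gm, blocks)
    n_multi = sum(1 for m in markers if m.n_snps > 1)
    counts = [m.n_alleles for m in markers if m.n_snps > 1]
    print(f"{len(blocks)} LD blocks -> {len(markers)} SNPLDB markers "
          f"({n_multi} multi-SNP, alleles/block "
          f"{min(counts)}~{max(counts)})")
    io.write_markers(markers, ROOT / "markers")
    print(f"written to {ROOT / 'markers'}")


if __name__ == "__main__":
    main()
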