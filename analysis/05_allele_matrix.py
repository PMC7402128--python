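#!/usr/bin/env python
"""Organize QTL-alleles into matrices and compare the subpopulations.

Builds the accession x locus QTL-allele matrix for each indicator, tests
every locus for allele-frequency differentiation between the LR
(landrace-like) and RC (cultivar-like) subpopulations with a Pearson
chi-square, and lists the alleles excluded from or newly emerged in RC.
Writes matrices and reports under results/allele_matrix/.
"""

from pathlib import Path

import pandas as pd

from qtlallele import io
from qtlallele.allele_matrix import (
    allele_turnover,
    build_matrix,
    subpop_differentiation,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    markers = io.read_markers(ROOT / "markers")
    sp = io.read_table(ROOT / "synthetic" / "subpop.tsv")
    subpop = pd.Series(sp["subpop"].to_numpy(), index=sp["accession"])
    out = ROOT / "allele_matrix"

    for name in ("MPW", "MPH"):
        model = io.read_model(ROOT / "gwas" / f"model_{name}.tsv",
                              markers.accessions)
        mat = build_matrix(model, markers, subpop)
        comp = subpop_differentiation(mat)
        turn = allele_turnover(mat, "LR", "RC")
        tally = turn.tally()
        print(f"{name}: {len(mat.loci)} loci; "
              f"{comp.n_significant} differentiated at p<=0.05; "
              f"{tally['excluded']['total']} alleles excluded "
              f"({tally['excluded']['negative']} neg, "
              f"{tally['excluded']['positive']} pos), "
              f"{tally['emerged']['total']} emerged in RC")
        cells = mat.alleles.astype(str) + ":" + mat.effects.round(4).astype(str)
        cells.index.name = "accession"
        io.write_table(cells, out / f"matrix_{name}.tsv", index=True)
        io.write_table(comp.table, out / f"differentiation_{name}.tsv")
        io.write_table(turn.excluded, out / f"excluded_{name}.tsv")
        io.write_table(turn.emerged, out / f"emerged_{name}.tsv")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
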