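#!/usr/bin/env python
"""Compute the two drought-tolerance indicators and their heritabilities.

Reads the trial written by 01_simulate_panel.py, forms the per-replication
stress/non-stress ratios, rescales them to membership indices anchored at
the check means (MPW for plant weight, MPH for plant height), estimates
broad-sense heritability from the one-way ANOVA, and summarizes the two
indicators per subpopulation.  Writes indicators.tsv and summary.tsv
under results/phenotype/.
"""

from pathlib import Path

import pandas as pd

from qtlallele import io
from qtlallele.phenotype import (
    anova_heritability,
    membership_index,
    relative_trait,
    summarize_indicators,
)
from qtlallele.pipeline import INDICATOR_OF

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trial = io.read_trial_csv(ROOT / "synthetic" / "trial.csv")
    tol, sen = io.read_checks(ROOT / "synthetic" / "checks.tsv")
    sp = io.read_table(ROOT / "synthetic" / "subpop.tsv")
    subpop = pd.Series(sp["subpop"].to_numpy(), index=sp["accession"])
    out = ROOT / "phenotype"

    cols, h2 = {}, {}
    for trait, name in INDICATOR_OF.items():
        res = membership_index(relative_trait(trial, trait), tol, sen)
        est = anova_heritability(res.M)
        cols[name] = res.accession_mean
        h2[name] = est.h2
        print(f"{name}: h2 = {est.h2:.3f} "
              f"(sigma2_g = {est.sigma2_g:.4f}, sigma2_e = {est.sigma2_e:.4f}, "
              f"r = {est.r:.0f})")

    ind = pd.DataFrame(cols)
    ind["subpop"] = subpop.loc[ind.index]
    summary = summarize_indicators(ind["MPW"], ind["MPH"], subpop)
    print(f"corr(MPW, MPH) = {summary.correlation:.2f} "
          f"(p = {summary.correlation_p:.2g})")
    print(f"most tolerant: {summary.top[:5]} ...")

    io.write_table(ind.reset_index(names="accession"), out / "indicators.tsv")
    io.write_table(summary.per_subpop, out / "summary.tsv")
    io.write_table(pd.DataFrame([h2]), out / "heritability.tsv")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
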