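"""Published reference results for the 564-accession Chinese soybean
drought-tolerance panel.

The panel itself is not deposited, but the study's summary tables are:
the per-locus QTL summaries for the two indicators (MPW, membership index
of relative plant weight; MPH, of relative plant height), and the
ten best predicted crosses with their progeny 95th-percentile values.
These transcriptions back the worked-example arithmetic (variance
bookkeeping, weighted-average values) and give realistic targets for the
synthetic generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# ANOVA heritabilities of the two indicators, in percent
H2_PERCENT = {"MPW": 81.3, "MPH": 76.0}

# R^2 threshold (percent) separating large- from small-contribution QTL
LC_MAJOR_THRESHOLD = 1.0

PANEL_SIZE = 564
N_LANDRACES = 319
N_CULTIVARS = 245


def _read(name: str) -> pd.DataFrame:
    with resources.files("qtlallele.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_qtl_table(indicator: str) -> pd.DataFrame:
    """Per-locus QTL summary (marker, allele count, -log10 p, R^2 %) for
    one indicator; ``shared`` flags loci detected for both indicators."""
    indicator = indicator.upper()
    if indicator not in ("MPW", "MPH"):
        raise ValueError("indicator must be 'MPW' or 'MPH'")
    df = _read(f"qtl_{indicator.lower()}.tsv")
    df["shared"] = df["shared"].astype(bool)
    return df


def load_cross_table() -> pd.DataFrame:
    """The ten top-ranked predicted crosses: parental indicator values with
    positive/negative allele counts, progeny 95th percentiles, and WAV."""
    return _read("optimal_crosses.tsv")


def qtl_system_summary(
    mpw: pd.DataFrame | None = None,
    mph: pd.DataFrame | None = None,
    h2_percent: dict[str, float] | None = None,
    lc_threshold: float = LC_MAJOR_THRESHOLD,
) -> dict:
    """Variance bookkeeping of a detected QTL-allele system.

    For each indicator: total R^2 of all loci, of the large-contribution
    (R^2 >= threshold) and small-contribution groups, the unmapped minor
    share (heritability minus total R^2), and each group's portion of the
    detected contribution.  Union counts deduplicate loci and alleles
    shared between the indicators.
    """
    from .allele_matrix import percentage_share, unmapped_minor_share

    mpw = load_qtl_table("MPW") if mpw is None else mpw
    mph = load_qtl_table("MPH") if mph is None else mph
    h2 = dict(H2_PERCENT if h2_percent is None else h2_percent)
    out: dict = {}
    for name, df in (("MPW", mpw), ("MPH", mph)):
        lc = df[df["r2_percent"] >= lc_threshold]
        sc = df[df["r2_percent"] < lc_threshold]
        total = round(float(df["r2_percent"].sum()), 1)
        out[name] = {
            "n_qtl": len(df),
            "n_alleles": int(df["n_alleles"].sum()),
            "total_r2": total,
            "lc_n": len(lc),
            "lc_r2": round(float(lc["r2_percent"].sum()), 1),
            "sc_n": len(sc),
            "sc_r2": round(float(sc["r2_percent"].sum()), 1),
            "h2": h2[name],
            "unmapped_r2": unmapped_minor_share(h2[name], total),
            "whole_portion_of_h2": percentage_share(total, h2[name]),
            "lc_portion": percentage_share(
                float(lc["r2_percent"].sum()), total
            ),
            "sc_portion": percentage_share(
                float(sc["r2_percent"].sum()), total
            ),
        }
    shared_markers = set(mpw["marker"]) & set(mph["marker"])
    n_shared = len(shared_markers)
    shared_alleles = int(
        mpw.loc[mpw["marker"].isin(shared_markers), "n_alleles"].sum()
    )
    out["union"] = {
        "n_shared_qtl": n_shared,
        "n_qtl_total": len(mpw) + len(mph) - n_shared,
        "n_shared_alleles": shared_alleles,
        "n_alleles_total": int(mpw["n_alleles"].sum())
        + int(mph["n_alleles"].sum())
        - shared_alleles,
    }
    return out
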