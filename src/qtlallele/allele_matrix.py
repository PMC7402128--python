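"""QTL-allele matrices, subpopulation differentiation, and allele turnover.

The QTL-allele matrix is the compact genetic structure of the panel for
one indicator: rows are accessions, columns the detected loci, and each
cell holds the carried allele together with its estimated effect.  Adding
the model intercept to a row sum gives the accession's predicted
indicator value.  The landrace (ancestral) vs released-cultivar (derived)
subpopulations are compared locus by locus with a Pearson chi-square test
on the allele-count table, and turnover lists record the alleles lost
(excluded) or gained (emerged) in the derived subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import StepwiseModel
from .errors import DataError
from .snpldb import MarkerSet


@dataclass
class QTLAlleleMatrix:
    accessions: list[str]
    subpop: pd.Series
    loci: list[str]
    alleles: pd.DataFrame  # accession x locus allele code
    effects: pd.DataFrame  # accession x locus carried-allele effect
    intercept: float
    allele_labels: dict[str, dict[int, str]]

    def row_sums(self) -> pd.Series:
        return self.effects.sum(axis=1)

    def predicted_values(self) -> pd.Series:
        """intercept + row sum of effects (covariates at population mean)."""
        return (self.intercept + self.row_sums()).rename("predicted")

    def positive_negative_counts(self) -> pd.DataFrame:
        """Per-accession counts of carried positive and negative alleles
        (exact zeros counted as neither)."""
        eff = self.effects.to_numpy()
        return pd.DataFrame(
            {
                "n_positive": (eff > 0).sum(axis=1),
                "n_negative": (eff < 0).sum(axis=1),
            },
            index=self.accessions,
        )

    def allele_frequencies(self, locus: str) -> pd.DataFrame:
        """Allele frequency table (rows: allele code) per subpopulation."""
        codes = self.alleles[locus]
        tab = pd.crosstab(codes, self.subpop.loc[self.accessions])
        return tab / tab.sum(axis=0)


def build_matrix(
    model: StepwiseModel,
    markers: MarkerSet,
    subpop: pd.Series,
) -> QTLAlleleMatrix:
    """Populate the accession x locus matrix of carried alleles and effects."""
    missing = [mid for mid in model.loci if not _has_marker(markers, mid)]
    if missing:
        raise DataError(f"model loci missing from marker set: {missing}")
    acc = list(markers.accessions)
    unknown = set(acc) - set(subpop.index)
    if unknown:
        raise DataError(f"accessions without subpopulation label: {sorted(unknown)[:5]}")
    allele_cols = {}
    effect_cols = {}
    labels = {}
    for mid in model.loci:
        m = markers.by_id(mid)
        eff = model.locus_results[mid].allele_effects
        allele_cols[mid] = m.codes.astype(int)
        effect_cols[mid] = np.array([eff[int(c)] for c in m.codes])
        labels[mid] = model.locus_results[mid].allele_labels
    return QTLAlleleMatrix(
        accessions=acc,
        subpop=subpop.loc[acc],
        loci=list(model.loci),
        alleles=pd.DataFrame(allele_cols, index=acc),
        effects=pd.DataFrame(effect_cols, index=acc),
        intercept=model.intercept,
        allele_labels=labels,
    )


def _has_marker(markers: MarkerSet, mid: str) -> bool:
    try:
        markers.by_id(mid)
        return True
    except KeyError:
        return False


@dataclass
class SubpopComparison:
    table: pd.DataFrame  # locus, chi2, df, p, p_bh, significant, low_expected
    alpha: float
    n_significant: int


def subpop_differentiation(
    matrix: QTLAlleleMatrix, alpha: float = 0.05
) -> SubpopComparison:
    """Pearson chi-square (no continuity correction) of allele counts
    between subpopulations at every locus.

    Loci with any expected cell below 5 are flagged, not dropped.  A
    Benjamini-Hochberg column is reported alongside the raw decisions.
    """
    labels = matrix.subpop
    counts = labels.value_counts()
    if (counts < 1).any() or len(counts) < 2:
        raise DataError("need at least two non-empty subpopulations")
    rows = []
    for locus in matrix.loci:
        tab = pd.crosstab(matrix.alleles[locus], labels)
        if tab.shape[0] < 2:
            chi2, p, dof, exp = 0.0, 1.0, 0, np.full(tab.shape, np.nan)
        else:
            chi2, p, dof, exp = stats.chi2_contingency(
                tab.to_numpy(), correction=False
            )
        rows.append(
            {
                "locus": locus,
                "chi2": float(chi2),
                "df": int(dof),
                "p": float(p),
                "significant": bool(p <= alpha),
                "low_expected": bool(np.nanmin(exp) < 5) if tab.shape[0] >= 2 else True,
            }
        )
    table = pd.DataFrame(rows)
    # Benjamini-Hochberg adjusted p-values
    p = table["p"].to_numpy()
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        k = m - rank_from_end
        prev = min(prev, p[i] * m / k)
        adj[i] = prev
    table["p_bh"] = adj
    return SubpopComparison(
        table=table,
        alpha=alpha,
        n_significant=int(table["significant"].sum()),
    )


@dataclass
class AlleleTurnover:
    """Alleles excluded from, or newly emerged in, the derived subpopulation."""

    excluded: pd.DataFrame  # locus, allele, label, effect, sign
    emerged: pd.DataFrame
    n_loci_changed: int

    def tally(self) -> dict:
        def split(df: pd.DataFrame) -> dict:
            return {
                "total": len(df),
                "positive": int((df["effect"] > 0).sum()),
                "negative": int((df["effect"] < 0).sum()),
            }

        return {"excluded": split(self.excluded), "emerged": split(self.emerged)}


def allele_turnover(
    matrix: QTLAlleleMatrix,
    ancestral: str,
    derived: str,
) -> AlleleTurnover:
    """Excluded = carried in the ancestral group only; emerged = in the
    derived group only.  Tallies are split by effect sign."""
    for lab in (ancestral, derived):
        if lab not in set(matrix.subpop):
            raise DataError(f"unknown subpopulation label {lab!r}")
    exc_rows, eme_rows = [], []
    anc_mask = (matrix.subpop == ancestral).to_numpy()
    der_mask = (matrix.subpop == derived).to_numpy()
    changed_loci = set()
    for locus in matrix.loci:
        codes = matrix.alleles[locus].to_numpy()
        eff_map = {}
        for c, e in zip(codes, matrix.effects[locus].to_numpy()):
            eff_map[int(c)] = float(e)
        anc = set(codes[anc_mask].tolist())
        der = set(codes[der_mask].tolist())
        for code in sorted(anc - der):
            exc_rows.append(_turnover_row(matrix, locus, code, eff_map))
            changed_loci.add(locus)
        for code in sorted(der - anc):
            eme_rows.append(_turnover_row(matrix, locus, code, eff_map))
            changed_loci.add(locus)
    cols = ["locus", "allele", "label", "effect", "sign"]
    return AlleleTurnover(
        excluded=pd.DataFrame(exc_rows, columns=cols),
        emerged=pd.DataFrame(eme_rows, columns=cols),
        n_loci_changed=len(changed_loci),
    )


def _turnover_row(matrix, locus, code, eff_map) -> dict:
    e = eff_map[code]
    return {
        "locus": locus,
        "allele": int(code),
        "label": matrix.allele_labels[locus].get(int(code), str(code)),
        "effect": e,
        "sign": "positive" if e > 0 else ("negative" if e < 0 else "zero"),
    }


def percentage_share(part: float, whole: float, ndigits: int = 1) -> float:
    """100 * part / whole, rounded — the portion bookkeeping used in the
    QTL-system summary tables."""
    if whole == 0:
        raise DataError("whole must be non-zero")
    return round(100.0 * part / whole, ndigits)


def unmapped_minor_share(h2_percent: float, total_r2_percent: float,
                         ndigits: int = 1) -> float:
    """Phenotypic-variance share left to collective unmapped minor QTL:
    heritability minus the summed contribution of detected QTL (both in
    percent)."""
    return round(h2_percent - total_r2_percent, ndigits)
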