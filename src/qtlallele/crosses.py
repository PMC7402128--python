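"""Optimal-cross prediction by progeny simulation on QTL-allele matrices.

Progenies of a biparental cross are modeled as fully homozygous derived
lines: at every locus of the union of the trait matrices a progeny
inherits parent 1's or parent 2's allele with probability 1/2,
independently across loci (free recombination); loci shared between
traits are sampled once per progeny so the two trait values stay
genetically consistent.  A progeny's trait value is that trait's model
intercept plus the summed effects of the inherited alleles.  Crosses are
ranked by the heritability-weighted average (WAV) of their progeny 95th
percentiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .allele_matrix import QTLAlleleMatrix
from .errors import DataError

# heritabilities of the two indicators in the reference soybean panel,
# the default WAV weights
H2_MPW = 0.813
H2_MPH = 0.760


def n_crosses(n_accessions: int) -> int:
    """Number of unordered distinct biparental crosses, n(n-1)/2."""
    return n_accessions * (n_accessions - 1) // 2


def enumerate_crosses(accessions: Iterable[str]) -> Iterator[tuple[str, str]]:
    """All unordered distinct parent pairs."""
    acc = list(accessions)
    if len(acc) < 2:
        raise DataError("need at least 2 accessions to enumerate crosses")
    return itertools.combinations(acc, 2)


@dataclass
class ProgenySample:
    parents: tuple[str, str]
    n: int
    seed: int
    values: dict[str, np.ndarray]  # trait -> per-progeny predicted values


def simulate_progeny(
    cross: tuple[str, str],
    matrices: Mapping[str, QTLAlleleMatrix],
    n: int = 10_000,
    seed: int = 0,
) -> ProgenySample:
    """Simulate n homozygous derived-line progenies of one cross."""
    p1, p2 = cross
    loci_union: list[tuple[str, str]] = []  # (trait-scope key) -> columns
    seen: dict[str, int] = {}
    for trait, mat in matrices.items():
        for acc in (p1, p2):
            if acc not in mat.alleles.index:
                raise DataError(f"parent {acc} missing from {trait} matrix")
        for locus in mat.loci:
            if locus not in seen:
                seen[locus] = len(seen)
    rng = np.random.default_rng(seed)
    # one inheritance draw per progeny per union locus
    take_p2 = rng.random((n, len(seen))) < 0.5

    values: dict[str, np.ndarray] = {}
    for trait, mat in matrices.items():
        e1 = mat.effects.loc[p1, mat.loci].to_numpy(dtype=float)
        e2 = mat.effects.loc[p2, mat.loci].to_numpy(dtype=float)
        cols = [seen[locus] for locus in mat.loci]
        tp2 = take_p2[:, cols]
        vals = mat.intercept + np.where(tp2, e2[None, :], e1[None, :]).sum(axis=1)
        values[trait] = vals
    return ProgenySample(parents=(p1, p2), n=n, seed=seed, values=values)


def percentile_summary(sample: np.ndarray, q: float = 95.0) -> float:
    """Linear-interpolation percentile of a progeny sample."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise DataError("empty progeny sample")
    return float(np.percentile(sample, q, method="linear"))


def weighted_average_value(
    value_mpw: float,
    value_mph: float,
    h2_mpw: float = H2_MPW,
    h2_mph: float = H2_MPH,
) -> float:
    """Heritability-weighted average of the two indicator values:
    (h2_mpw * v_mpw + h2_mph * v_mph) / (h2_mpw + h2_mph).

    Reported to three decimals in the cross tables.
    """
    for v in (value_mpw, value_mph):
        if not np.isfinite(v):
            raise DataError("non-finite indicator value in WAV")
    if h2_mpw <= 0 or h2_mph <= 0:
        raise DataError("WAV weights must be positive")
    return (h2_mpw * value_mpw + h2_mph * value_mph) / (h2_mpw + h2_mph)


@dataclass
class CrossRanking:
    table: pd.DataFrame
    criterion: str
    q: float
    n_progeny: int

    def optimal(self) -> pd.DataFrame:
        return self.table[self.table["optimal"]]


def predict_crosses(
    matrices: Mapping[str, QTLAlleleMatrix],
    crosses: Iterable[tuple[str, str]] | None = None,
    observed: Mapping[str, pd.Series] | None = None,
    n_progeny: int = 10_000,
    q: float = 95.0,
    criterion: str = "exceeds_population_max",
    joint: bool = True,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
) -> CrossRanking:
    """Simulate all crosses, summarize progeny percentiles, and flag the
    optimal ones.

    criterion 'exceeds_population_max' compares each trait's progeny
    percentile with the maximum observed (or predicted) value in the
    whole panel; 'exceeds_parental_max' compares with the higher of the
    two parents.  With ``joint`` the requirement must hold for every
    trait simultaneously.  Ranking is by the weighted average (WAV) of
    the per-trait percentiles, descending, ties broken by cross id.
    """
    if criterion not in ("exceeds_population_max", "exceeds_parental_max"):
        raise DataError(f"unknown criterion {criterion!r}")
    traits = list(matrices)
    if weights is None:
        weights = {t: w for t, w in zip(traits, (H2_MPW, H2_MPH))}
    ref_values = {}
    for t in traits:
        ref_values[t] = (
            observed[t] if observed is not None else matrices[t].predicted_values()
        )
    pop_max = {t: float(ref_values[t].max()) for t in traits}

    any_mat = matrices[traits[0]]
    if crosses is None:
        crosses = enumerate_crosses(any_mat.accessions)
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, (p1, p2) in enumerate(crosses):
        child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        sample = simulate_progeny((p1, p2), matrices, n=n_progeny, seed=child_seed)
        row = {"parent1": p1, "parent2": p2}
        ok = [] if joint else [False]
        flags = []
        for t in traits:
            pct = percentile_summary(sample.values[t], q)
            row[f"{t}_p{q:g}"] = pct
            parental_max = max(
                float(ref_values[t].loc[p1]), float(ref_values[t].loc[p2])
            )
            row[f"{t}_parent_max"] = parental_max
            threshold = (
                pop_max[t]
                if criterion == "exceeds_population_max"
                else parental_max
            )
            flags.append(pct > threshold)
        row["optimal"] = all(flags) if joint else any(flags)
        vals = [row[f"{t}_p{q:g}"] for t in traits]
        w = [weights[t] for t in traits]
        row["wav"] = float(np.average(vals, weights=w))
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["wav", "parent1", "parent2"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return CrossRanking(
        table=table, criterion=criterion, q=q, n_progeny=n_progeny
    )
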