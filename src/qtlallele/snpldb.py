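"""SNP quality control and multi-allele SNPLDB marker assembly.

A SNPLDB marker is a haplotype-block locus: consecutive SNPs in strong
linkage disequilibrium are collapsed into one multi-allele marker whose
alleles are the observed haplotypes of an inbred panel; SNPs outside any
block are carried along as ordinary two-allele markers.  Blocks are found
with the confidence-interval (Gabriel-style) pair classification on |D'|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

# genotype call codes (inbred panel: hom calls dominate)
REF_HOM = 0
HET = 1
ALT_HOM = 2
MISSING = -1

_VALID_CODES = frozenset({REF_HOM, HET, ALT_HOM, MISSING})


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a panel of inbred accessions.

    ``calls`` is an int8 array of shape (n_snps, n_accessions) holding the
    codes REF_HOM/HET/ALT_HOM/MISSING.  ``snps`` has columns
    chrom, pos (1-based), ref, alt, with positions strictly increasing
    within each chromosome.
    """

    accessions: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.snps), len(self.accessions)):
            raise DataError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.accessions)} accessions"
            )
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise DataError(f"invalid genotype codes: {sorted(bad)}")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise DataError(f"positions not strictly increasing on {chrom}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.accessions), self.snps.copy(), self.calls.copy()
        )


def minor_allele_frequency(calls: np.ndarray) -> np.ndarray:
    """Per-SNP MAF from called genotypes (het counts one allele each way)."""
    calls = np.atleast_2d(calls)
    n_alt = 2 * (calls == ALT_HOM).sum(axis=1) + (calls == HET).sum(axis=1)
    n_called = 2 * (calls != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, n_alt / np.maximum(n_called, 1), 0.0)
    return np.minimum(p_alt, 1.0 - p_alt)


def qc_filter_snps(
    gm: GenotypeMatrix,
    max_missing_het: float = 0.30,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, dict]:
    """Drop SNPs failing the missing+het rate or MAF rule, then set het to missing.

    Returns the filtered matrix and a report dict with per-rule removal
    counts.  An empty result is allowed (reported, not an error).
    """
    if gm.n_snps == 0:
        raise DataError("empty genotype matrix")
    frac_bad = ((gm.calls == MISSING) | (gm.calls == HET)).mean(axis=1)
    maf = minor_allele_frequency(gm.calls)
    fail_rate = frac_bad > max_missing_het
    fail_maf = maf < min_maf
    keep = ~(fail_rate | fail_maf)
    calls = gm.calls[keep].copy()
    calls[calls == HET] = MISSING
    out = GenotypeMatrix(
        list(gm.accessions), gm.snps.loc[keep].reset_index(drop=True), calls
    )
    report = {
        "n_input": gm.n_snps,
        "n_removed_missing_het": int(fail_rate.sum()),
        "n_removed_maf": int(fail_maf.sum()),
        "n_removed": int((~keep).sum()),
        "n_kept": out.n_snps,
    }
    return out, report


def impute_missing(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, float]:
    """Fill missing calls with each SNP's major homozygous allele.

    Deterministic (ties go to the reference allele).  Returns the completed
    matrix and the fraction of calls imputed.
    """
    calls = gm.calls.copy()
    n_missing = int((calls == MISSING).sum())
    for i in range(gm.n_snps):
        row = calls[i]
        miss = row == MISSING
        if not miss.any():
            continue
        n_ref = int((row == REF_HOM).sum())
        n_alt = int((row == ALT_HOM).sum())
        if n_ref == 0 and n_alt == 0:
            raise DataError(f"SNP {i} has no called genotypes; cannot impute")
        row[miss] = REF_HOM if n_ref >= n_alt else ALT_HOM
    frac = n_missing / calls.size if calls.size else 0.0
    return GenotypeMatrix(list(gm.accessions), gm.snps.copy(), calls), frac


@dataclass(frozen=True)
class LDPairStats:
    """|D'| with a likelihood-grid confidence interval for one SNP pair."""

    dprime: float
    ci_low: float
    ci_high: float
    n_informative: int


_DPRIME_GRID = np.linspace(0.0, 1.0, 201)


def _haplotype_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """2x2 haplotype counts from homozygous calls of two SNPs (inbreds)."""
    ok = ((a == REF_HOM) | (a == ALT_HOM)) & ((b == REF_HOM) | (b == ALT_HOM))
    x = (a[ok] == ALT_HOM).astype(int)
    y = (b[ok] == ALT_HOM).astype(int)
    counts = np.zeros((2, 2))
    np.add.at(counts, (x, y), 1)
    return counts


def dprime_ci(
    a: np.ndarray, b: np.ndarray, confidence: float = 0.95
) -> LDPairStats:
    """|D'| and its CI for two SNPs, inbred calls read as haplotypes.

    The CI comes from the multinomial likelihood of the 2x2 haplotype table
    evaluated on a grid of |D'| in [0, 1] with the allele frequencies held
    at their observed values; bounds are the cumulative 5th and 95th
    percentiles of the normalized likelihood.
    """
    counts = _haplotype_counts(np.asarray(a), np.asarray(b))
    return dprime_ci_from_counts(counts, confidence)


def dprime_ci_from_counts(
    counts: np.ndarray, confidence: float = 0.95
) -> LDPairStats:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise DataError("no informative haplotypes for SNP pair")
    p = counts / n
    pa = p[1].sum()  # alt freq at first SNP
    pb = p[:, 1].sum()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise DataError("monomorphic SNP in D' computation")
    d = p[1, 1] - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
        sign = 1.0
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
        sign = -1.0
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    dprime = float(min(dprime, 1.0))

    # likelihood over the |D'| grid, D signed as observed
    dgrid = sign * _DPRIME_GRID * dmax
    p11 = pa * pb + dgrid
    p10 = pa * (1 - pb) - dgrid
    p01 = (1 - pa) * pb - dgrid
    p00 = (1 - pa) * (1 - pb) + dgrid
    probs = np.stack([p00, p01, p10, p11], axis=1)
    probs = np.clip(probs, 1e-12, None)
    obs = np.array([counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]])
    ll = (obs * np.log(probs)).sum(axis=1)
    lik = np.exp(ll - ll.max())
    cum = np.cumsum(lik) / lik.sum()
    # one-sided 5th / 95th cumulative-likelihood bounds (Haploview-style)
    tail = 1.0 - confidence
    lo = float(_DPRIME_GRID[int(np.searchsorted(cum, tail))])
    hi = float(_DPRIME_GRID[min(int(np.searchsorted(cum, confidence)), 200)])
    return LDPairStats(dprime, lo, hi, int(n))


@dataclass(frozen=True)
class LDBlock:
    """A haplotype block: a run of SNP indices on one chromosome."""

    chrom: str
    snp_indices: tuple[int, ...]  # global row indices into the matrix
    start: int  # bp, 1-based inclusive
    end: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def span(self) -> int:
        return self.end - self.start


def _classify_pair(
    stats: LDPairStats,
    strong_ld: tuple[float, float],
    recomb_high: float,
) -> str:
    lo_thr, hi_thr = strong_ld
    if stats.ci_low > lo_thr and stats.ci_high >= hi_thr:
        return "strong"
    if stats.ci_high < recomb_high:
        return "recomb"
    return "uninformative"


def find_ld_blocks(
    gm: GenotypeMatrix,
    max_dist: int = 200_000,
    min_maf: float = 0.01,
    strong_ld: tuple[float, float] = (0.70, 0.98),
    recomb_high: float = 0.90,
    frac_strong: float = 0.95,
) -> list[LDBlock]:
    """Confidence-interval haplotype-block detection.

    A candidate interval is one whose outermost SNP pair is in strong LD
    (CI low > 0.70 and CI high >= 0.98); it is accepted if, among its
    informative inner pairs (strong LD or strong recombination,
    CI high < 0.90), the strong-LD fraction is at least ``frac_strong``.
    Candidates are taken greedily from longest span to shortest without
    overlap; pairs farther apart than ``max_dist`` bp are never examined.
    """
    maf = minor_allele_frequency(gm.calls)
    blocks: list[LDBlock] = []
    for chrom, grp in gm.snps.groupby("chrom", sort=False):
        idx = [i for i in grp.index if maf[i] >= min_maf]
        if len(idx) < 2:
            continue
        pos = {i: int(gm.snps.at[i, "pos"]) for i in idx}
        cache: dict[tuple[int, int], str] = {}

        def classify(i: int, j: int) -> str:
            key = (i, j)
            if key not in cache:
                st = dprime_ci(gm.calls[i], gm.calls[j])
                cache[key] = _classify_pair(st, strong_ld, recomb_high)
            return cache[key]

        candidates = []
        for ai, i in enumerate(idx):
            for j in idx[ai + 1:]:
                if pos[j] - pos[i] > max_dist:
                    break
                if classify(i, j) == "strong":
                    candidates.append((i, j))
        # longest span first; ties by SNP count then leftmost
        def sort_key(c):
            i, j = c
            return (-(pos[j] - pos[i]), -(idx.index(j) - idx.index(i)), pos[i])

        used: set[int] = set()
        for i, j in sorted(candidates, key=sort_key):
            members = [k for k in idx if i <= k <= j]
            if any(k in used for k in members):
                continue
            n_strong = n_recomb = 0
            ok = True
            for ai, u in enumerate(members):
                for v in members[ai + 1:]:
                    if pos[v] - pos[u] > max_dist:
                        continue
                    cls = classify(u, v)
                    if cls == "strong":
                        n_strong += 1
                    elif cls == "recomb":
                        n_recomb += 1
            informative = n_strong + n_recomb
            ok = informative > 0 and n_strong / informative >= frac_strong
            if ok:
                blocks.append(
                    LDBlock(str(chrom), tuple(members), pos[i], pos[j])
                )
                used.update(members)
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


@dataclass
class Marker:
    """One SNPLDB marker: haplotype alleles over a block (or a single SNP).

    ``alleles`` are haplotype strings over the member SNPs ('0' = ref,
    '1' = alt), ordered by descending frequency; ``codes`` gives each
    accession's allele index.
    """

    id: str
    chrom: str
    start: int
    end: int
    snp_indices: tuple[int, ...]
    alleles: list[str]
    codes: np.ndarray

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    def allele_freqs(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.n_alleles) / len(self.codes)


@dataclass
class MarkerSet:
    accessions: list[str]
    markers: list[Marker]

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def by_id(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.id == marker_id:
                return m
        raise KeyError(marker_id)

    def code_matrix(self) -> np.ndarray:
        """(n_markers, n_accessions) allele-code matrix."""
        return np.stack([m.codes for m in self.markers])


def _merge_rare_haplotypes(
    haps: list[str], counts: dict[str, int], floor_count: float
) -> dict[str, str]:
    """Map each haplotype to its post-merge representative.

    Haplotypes below the floor are folded into the most similar frequent
    haplotype (minimum Hamming distance; ties broken by higher target
    frequency, then lexicographic order).
    """
    frequent = [h for h in haps if counts[h] >= floor_count]
    if not frequent:  # degenerate: keep the single most common haplotype
        frequent = [max(haps, key=lambda h: (counts[h], h))]
    mapping = {h: h for h in frequent}
    for h in haps:
        if h in mapping:
            continue
        best = min(
            frequent,
            key=lambda f: (
                sum(c1 != c2 for c1, c2 in zip(h, f)),
                -counts[f],
                f,
            ),
        )
        mapping[h] = best
    return mapping


def build_snpldb_markers(
    gm: GenotypeMatrix,
    blocks: Sequence[LDBlock],
    rare_allele_floor: float = 0.01,
) -> MarkerSet:
    """Encode LD blocks as multi-allele markers; SNPs outside blocks become
    two-allele markers.

    Requires a complete (imputed) matrix.  Haplotype alleles rarer than
    ``rare_allele_floor`` (as a frequency) are merged into their nearest
    frequent haplotype by Hamming distance.  Marker ids follow the
    ``<chrom>_BLOCK<k>`` / ``<chrom>_<pos>`` convention, with k counting
    multi-SNP markers per chromosome in genomic order.
    """
    if (gm.calls == MISSING).any() or (gm.calls == HET).any():
        raise DataError("marker assembly requires a complete homozygous matrix")
    n_acc = gm.n_accessions
    in_block = set()
    for b in blocks:
        for k in b.snp_indices:
            if k >= gm.n_snps:
                raise DataError(f"block references SNP index {k} outside matrix")
            in_block.add(k)

    entries: list[tuple[str, int, object]] = []  # (chrom, start, block-or-snp)
    for b in blocks:
        entries.append((b.chrom, b.start, b))
    for i in range(gm.n_snps):
        if i not in in_block:
            entries.append(
                (str(gm.snps.at[i, "chrom"]), int(gm.snps.at[i, "pos"]), i)
            )
    entries.sort(key=lambda e: (e[0], e[1]))

    markers: list[Marker] = []
    block_counter: dict[str, int] = {}
    for chrom, start, obj in entries:
        if isinstance(obj, LDBlock):
            block_counter[chrom] = block_counter.get(chrom, 0) + 1
            sub = gm.calls[list(obj.snp_indices)]  # (m, n_acc)
            hap_strings = [
                "".join("1" if c == ALT_HOM else "0" for c in sub[:, j])
                for j in range(n_acc)
            ]
            counts: dict[str, int] = {}
            for h in hap_strings:
                counts[h] = counts.get(h, 0) + 1
            mapping = _merge_rare_haplotypes(
                sorted(counts), counts, rare_allele_floor * n_acc
            )
            merged = [mapping[h] for h in hap_strings]
            mcounts: dict[str, int] = {}
            for h in merged:
                mcounts[h] = mcounts.get(h, 0) + 1
            alleles = sorted(mcounts, key=lambda h: (-mcounts[h], h))
            code_of = {h: k for k, h in enumerate(alleles)}
            codes = np.array([code_of[h] for h in merged], dtype=np.int16)
            markers.append(
                Marker(
                    id=f"{chrom}_BLOCK{block_counter[chrom]}",
                    chrom=chrom,
                    start=obj.start,
                    end=obj.end,
                    snp_indices=tuple(obj.snp_indices),
                    alleles=alleles,
                    codes=codes,
                )
            )
        else:
            i = obj
            pos = int(gm.snps.at[i, "pos"])
            calls = gm.calls[i]
            n_ref = int((calls == REF_HOM).sum())
            n_alt = n_acc - n_ref
            if n_alt == 0 or n_ref == 0:
                continue  # monomorphic singleton: not a marker
            if n_ref >= n_alt:
                alleles, code_map = ["0", "1"], {REF_HOM: 0, ALT_HOM: 1}
            else:
                alleles, code_map = ["1", "0"], {ALT_HOM: 0, REF_HOM: 1}
            codes = np.array([code_map[int(c)] for c in calls], dtype=np.int16)
            markers.append(
                Marker(
                    id=f"{chrom}_{pos}",
                    chrom=chrom,
                    start=pos,
                    end=pos,
                    snp_indices=(i,),
                    alleles=alleles,
                    codes=codes,
                )
            )
    return MarkerSet(list(gm.accessions), markers)
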