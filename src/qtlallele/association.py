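"""Restricted two-stage multi-locus multi-allele association scan.

Stage 1 tests each SNPLDB marker one at a time against the phenotype with
the structure eigenvectors as fixed covariates (partial F test of the
marker-as-categorical term) and pre-selects markers at a liberal
significance level.  Stage 2 runs forward-backward stepwise regression
over the pre-selected markers under a multi-locus multi-allele model,
with the total genetic contribution (model R^2 beyond the covariates)
capped at the trait heritability.  Per-allele effects use the unweighted
sum-to-zero parameterization within each locus, so an accession's
predicted value is the intercept plus the effects of its carried alleles
(covariates held at their population mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .similarity import EigenBasis
from .snpldb import Marker, MarkerSet


def _covariate_block(
    covariates: EigenBasis | np.ndarray | None, n: int
) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    C = covariates.vectors if isinstance(covariates, EigenBasis) else covariates
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise DataError("covariate rows do not match phenotype length")
    C = C - C.mean(axis=0)  # intercept = value at mean covariates
    if C.shape[1] and np.linalg.matrix_rank(C) < C.shape[1]:
        raise DataError("rank-deficient covariate matrix")
    return C


def _marker_dummies(
    marker: Marker, min_carriers: int
) -> tuple[np.ndarray, list[int], int] | None:
    """One-hot columns for a marker's non-reference alleles.

    Alleles with fewer than ``min_carriers`` carriers are folded into the
    reference (most frequent retained) allele.  Returns (dummies, retained
    allele codes ordered with the reference first, reference code), or
    None if fewer than two alleles are testable.
    """
    counts = np.bincount(marker.codes, minlength=marker.n_alleles)
    used = [a for a in range(marker.n_alleles) if counts[a] >= min_carriers]
    if len(used) < 2:
        return None
    ref = max(used, key=lambda a: counts[a])
    others = [a for a in used if a != ref]
    codes = marker.codes
    # fold rare alleles into the reference: they get no dummy column
    D = np.stack([(codes == a).astype(float) for a in others], axis=1)
    return D, [ref] + others, ref


def _qr_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (economy QR, rank-trimmed)."""
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _partial_f(
    y_res: np.ndarray, Z: np.ndarray, rss0: float, df_model: int, n: int
) -> tuple[float, float, float, int]:
    """F test of adding columns Z (already residualized) to a model with
    df_model parameters and residual sum of squares rss0."""
    Qz = _qr_basis(Z)
    df1 = Qz.shape[1]
    if df1 == 0 or rss0 <= 0.0:
        return 0.0, 1.0, rss0, df1
    proj = Qz.T @ y_res
    rss1 = max(rss0 - float(proj @ proj), 0.0)
    df2 = n - df_model - df1
    if df2 <= 0:
        return np.inf, 0.0, rss1, df1
    f = ((rss0 - rss1) / df1) / (rss1 / df2) if rss1 > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), max(p, np.nextafter(0, 1)), rss1, df1


@dataclass
class AssocScanResult:
    table: pd.DataFrame  # marker, n_alleles, F, p, neg_log10_p
    preselected: list[str]
    alpha: float
    skipped: list[str] = field(default_factory=list)


def stage1_scan(
    markers: MarkerSet,
    phenotype: pd.Series,
    covariates: EigenBasis | np.ndarray | None = None,
    alpha: float = 0.05,
    min_carriers: int = 3,
) -> AssocScanResult:
    """Single-locus pre-selection: phenotype ~ covariates + marker."""
    y = phenotype.loc[markers.accessions].to_numpy(dtype=float)
    n = len(y)
    C = _covariate_block(covariates, n)
    Q0 = _qr_basis(np.column_stack([np.ones(n), C]))
    y_res = y - Q0 @ (Q0.T @ y)
    rss0 = float(y_res @ y_res)
    p0 = Q0.shape[1]

    rows = []
    skipped = []
    for m in markers:
        dum = _marker_dummies(m, min_carriers)
        if dum is None:
            skipped.append(m.id)
            continue
        D, used, _ = dum
        Z = D - Q0 @ (Q0.T @ D)
        f, p, _, df1 = _partial_f(y_res, Z, rss0, p0, n)
        rows.append((m.id, len(used), f, p, -np.log10(p)))
    table = pd.DataFrame(
        rows, columns=["marker", "n_alleles", "F", "p", "neg_log10_p"]
    )
    preselected = list(table.loc[table["p"] <= alpha, "marker"])
    return AssocScanResult(table, preselected, alpha, skipped)


@dataclass
class LocusResult:
    marker: str
    partial_r2: float
    neg_log10_p: float
    allele_effects: dict[int, float]  # allele code -> effect (sum-to-zero)
    allele_labels: dict[int, str]
    n_alleles: int = 2  # retained (testable) alleles
    reference_code: int = 0


@dataclass
class StepwiseModel:
    """Final multi-locus multi-allele model."""

    loci: list[str]  # selection order
    locus_results: dict[str, LocusResult]
    intercept: float
    covariate_coefs: np.ndarray
    total_r2: float
    h2_cap: float
    n: int
    accessions: list[str]

    @property
    def unmapped_share(self) -> float:
        """Heritability not captured by the selected loci (collective
        unmapped minor QTL)."""
        return self.h2_cap - self.total_r2

    def allele_effect(self, marker_id: str, allele_code: int) -> float:
        return self.locus_results[marker_id].allele_effects[allele_code]

    def predict(self, markers: MarkerSet) -> pd.Series:
        """Predicted phenotype per accession at mean covariates."""
        vals = np.full(len(markers.accessions), self.intercept)
        for mid in self.loci:
            m = markers.by_id(mid)
            eff = self.locus_results[mid].allele_effects
            vals += np.array([eff[int(c)] for c in m.codes])
        return pd.Series(vals, index=markers.accessions)


def _design_for(
    markers: MarkerSet, loci: list[str], min_carriers: int
) -> tuple[np.ndarray, list[tuple[str, list[int], int]]]:
    cols = []
    meta = []
    for mid in loci:
        m = markers.by_id(mid)
        dum = _marker_dummies(m, min_carriers)
        if dum is None:
            raise DataError(f"selected locus {mid} has <2 testable alleles")
        D, used, ref = dum
        cols.append(D)
        meta.append((mid, used, ref))
    X = np.hstack(cols) if cols else np.empty((len(markers.accessions), 0))
    return X, meta


def stage2_stepwise(
    markers: MarkerSet,
    candidate_ids: list[str],
    phenotype: pd.Series,
    covariates: EigenBasis | np.ndarray | None = None,
    h2_cap: float = 1.0,
    alpha_entry: float = 0.01,
    alpha_stay: float = 0.01,
    min_carriers: int = 3,
) -> StepwiseModel:
    """Forward-backward stepwise selection capped at the heritability.

    At each forward step the candidate with the smallest partial-F p-value
    (ties: larger partial R^2, then genomic order) enters if p <=
    ``alpha_entry`` and the resulting genetic R^2 stays within ``h2_cap``;
    after each entry, included loci with partial p > ``alpha_stay`` are
    backward-eliminated.  The final refit provides the intercept,
    covariate coefficients and sum-to-zero allele effects.
    """
    if not (0.0 <= h2_cap <= 1.0):
        raise DataError("h2_cap must lie in [0, 1]")
    y = phenotype.loc[markers.accessions].to_numpy(dtype=float)
    n = len(y)
    C = _covariate_block(covariates, n)
    base = np.column_stack([np.ones(n), C])
    tss = float(((y - y.mean()) ** 2).sum())
    Q0 = _qr_basis(base)
    if tss == 0:  # constant phenotype: nothing to select
        rss_cov0 = float(y @ y - (Q0.T @ y) @ (Q0.T @ y))
        return _final_fit(markers, [], y, C, 1.0, rss_cov0, h2_cap, min_carriers)
    rss_cov = float(y @ y - (Q0.T @ y) @ (Q0.T @ y))

    order = {mid: i for i, mid in enumerate(m.id for m in markers)}
    candidates = [mid for mid in candidate_ids if mid in order]
    dummies: dict[str, tuple[np.ndarray, list[int], int]] = {}
    for mid in candidates:
        dum = _marker_dummies(markers.by_id(mid), min_carriers)
        if dum is not None:
            dummies[mid] = dum
    candidates = [mid for mid in candidates if mid in dummies]

    selected: list[str] = []

    def current_design(loci: list[str]) -> np.ndarray:
        cols = [base] + [dummies[mid][0] for mid in loci]
        return np.hstack(cols)

    while True:
        X = current_design(selected)
        Q = _qr_basis(X)
        p_now = Q.shape[1]
        y_res = y - Q @ (Q.T @ y)
        rss_now = float(y_res @ y_res)
        # score all remaining candidates
        scored = []
        for mid in candidates:
            if mid in selected:
                continue
            D = dummies[mid][0]
            Z = D - Q @ (Q.T @ D)
            f, p, rss_new, df1 = _partial_f(y_res, Z, rss_now, p_now, n)
            if df1 == 0:
                continue
            if n - p_now - df1 <= 1:
                warnings.warn(
                    "stepwise selection stopped: degrees of freedom exhausted",
                    stacklevel=2,
                )
                scored = []
                break
            scored.append((p, -(rss_now - rss_new), order[mid], mid, rss_new))
        entered = False
        for p, neg_gain, _, mid, rss_new in sorted(scored):
            if p > alpha_entry:
                break
            r2_new = (rss_cov - rss_new) / tss
            if r2_new > h2_cap + 1e-9:
                continue  # would exceed the heritability cap; try next best
            selected.append(mid)
            entered = True
            break
        if not entered:
            break
        # backward elimination
        while len(selected) > 1:
            X_full = current_design(selected)
            Qf = _qr_basis(X_full)
            rss_full = float(y @ y - (Qf.T @ y) @ (Qf.T @ y))
            worst = None
            for mid in selected:
                rest = [s for s in selected if s != mid]
                Xr = current_design(rest)
                Qr = _qr_basis(Xr)
                yr = y - Qr @ (Qr.T @ y)
                rss_r = float(yr @ yr)
                D = dummies[mid][0]
                Z = D - Qr @ (Qr.T @ D)
                _, p, _, _ = _partial_f(yr, Z, rss_r, Qr.shape[1], n)
                if worst is None or p > worst[0]:
                    worst = (p, mid)
            if worst is not None and worst[0] > alpha_stay:
                selected.remove(worst[1])
            else:
                break

    return _final_fit(
        markers, selected, y, C, tss, rss_cov, h2_cap, min_carriers
    )


def _final_fit(
    markers: MarkerSet,
    selected: list[str],
    y: np.ndarray,
    C: np.ndarray,
    tss: float,
    rss_cov: float,
    h2_cap: float,
    min_carriers: int,
) -> StepwiseModel:
    n = len(y)
    base = np.column_stack([np.ones(n), C])
    X_loci, meta = _design_for(markers, selected, min_carriers)
    X = np.hstack([base, X_loci])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(((y - X @ beta) ** 2).sum())
    total_r2 = (rss_cov - rss_full) / tss if selected and tss > 0 else 0.0

    intercept = float(beta[0])
    cov_coefs = beta[1 : 1 + C.shape[1]].copy()
    locus_results: dict[str, LocusResult] = {}
    col = 1 + C.shape[1]
    Qf = _qr_basis(X)
    for mid, used, ref in meta:
        m = markers.by_id(mid)
        a = len(used)  # retained alleles incl. reference
        coefs = np.concatenate([[0.0], beta[col : col + a - 1]])
        shift = coefs.mean()
        effects = {
            code: float(c - shift) for code, c in zip(used, coefs)
        }
        intercept += float(shift)
        # fold dropped alleles onto the reference effect
        for code in range(m.n_alleles):
            if code not in effects:
                effects[code] = effects[ref]
        # partial F of the locus given everything else
        rest = [s for s in selected if s != mid]
        Xr_loci, _ = _design_for(markers, rest, min_carriers)
        Qr = _qr_basis(np.hstack([base, Xr_loci]))
        yr = y - Qr @ (Qr.T @ y)
        rss_r = float(yr @ yr)
        D = _marker_dummies(m, min_carriers)[0]
        Z = D - Qr @ (Qr.T @ D)
        _, p, _, _ = _partial_f(yr, Z, rss_r, Qr.shape[1], n)
        locus_results[mid] = LocusResult(
            marker=mid,
            partial_r2=float((rss_r - rss_full) / tss) if tss > 0 else 0.0,
            neg_log10_p=float(-np.log10(p)),
            allele_effects=effects,
            allele_labels={i: lab for i, lab in enumerate(m.alleles)},
            n_alleles=a,
            reference_code=ref,
        )
        col += a - 1

    assert total_r2 <= h2_cap + 1e-9, "heritability cap violated"
    return StepwiseModel(
        loci=list(selected),
        locus_results=locus_results,
        intercept=intercept,
        covariate_coefs=cov_coefs,
        total_r2=float(total_r2),
        h2_cap=float(h2_cap),
        n=n,
        accessions=list(markers.accessions),
    )


def estimate_allele_effects(
    markers: MarkerSet,
    loci: list[str],
    phenotype: pd.Series,
    locus: str,
    covariates: EigenBasis | np.ndarray | None = None,
    min_carriers: int = 3,
) -> dict[int, float]:
    """Sum-to-zero allele effects of one locus in a fixed multi-locus model.

    The effect of allele a is the deviation of allele-a carriers from the
    locus mean, adjusted for the other model terms.
    """
    if locus not in loci:
        raise DataError(f"locus {locus} not in the supplied model loci")
    y = phenotype.loc[markers.accessions].to_numpy(dtype=float)
    C = _covariate_block(covariates, len(y))
    tss = float(((y - y.mean()) ** 2).sum())
    Q0 = _qr_basis(np.column_stack([np.ones(len(y)), C]))
    rss_cov = float(y @ y - (Q0.T @ y) @ (Q0.T @ y))
    model = _final_fit(markers, list(loci), y, C, tss, rss_cov, 1.0, min_carriers)
    return model.locus_results[locus].allele_effects


def locus_contribution(model: StepwiseModel) -> pd.DataFrame:
    """Per-locus partial R^2 (type-III style) plus the total and the
    unmapped minor-QTL share (h2 cap minus total R^2)."""
    rows = [
        {
            "marker": mid,
            "n_alleles": model.locus_results[mid].n_alleles,
            "partial_r2": model.locus_results[mid].partial_r2,
            "neg_log10_p": model.locus_results[mid].neg_log10_p,
        }
        for mid in model.loci
    ]
    df = pd.DataFrame(
        rows, columns=["marker", "n_alleles", "partial_r2", "neg_log10_p"]
    )
    df.attrs["total_r2"] = model.total_r2
    df.attrs["unmapped_share"] = model.unmapped_share
    return df
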