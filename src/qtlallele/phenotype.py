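"""Membership-index stress-tolerance indicators from replicated two-regime
trials.

For each accession i and replication k the relative trait value is
X_ik = value(stress) / value(non-stress).  The membership index

    M_ik = (X_ik - X_kS) / (X_kT - X_kS)

rescales X within each replication so the sensitive-check mean X_kS maps
to 0 and the tolerant-check mean X_kT maps to 1; larger M means stronger
tolerance, and values outside [0, 1] indicate accessions beyond the
checks.  The accession's indicator (MPW for plant weight, MPH for plant
height) is the mean of M_ik over replications.  Broad-sense heritability
comes from a one-way random-effects ANOVA with accessions as the factor:
h2 = s2_g / (s2_g + s2_e / r) on the replication-mean basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateCheckError

REGIMES = ("stress", "nonstress")


def validate_trial(data: pd.DataFrame) -> None:
    required = {"accession", "replication", "regime", "trait", "value"}
    missing = required - set(data.columns)
    if missing:
        raise DataError(f"trial table missing columns: {sorted(missing)}")
    bad = set(data["regime"]) - set(REGIMES)
    if bad:
        raise DataError(f"unknown regimes: {sorted(bad)}")
    if (data["value"] <= 0).any():
        n = int((data["value"] <= 0).sum())
        raise DataError(f"{n} non-positive trait values in trial table")


def relative_trait(data: pd.DataFrame, trait: str) -> pd.DataFrame:
    """X_ik = stress / non-stress per (accession, replication) for one trait.

    Returns a DataFrame indexed by accession with one column per
    replication.
    """
    validate_trial(data)
    sub = data[data["trait"] == trait]
    if sub.empty:
        raise DataError(f"no records for trait {trait!r}")
    wide = sub.pivot_table(
        index=["accession", "replication"],
        columns="regime",
        values="value",
        aggfunc="mean",
    )
    incomplete = wide[wide.isna().any(axis=1)]
    if len(incomplete):
        cells = list(incomplete.index[:10])
        raise DataError(
            f"missing stress/non-stress pair for {len(incomplete)} "
            f"(accession, replication) cells, e.g. {cells}"
        )
    x = (wide["stress"] / wide["nonstress"]).unstack("replication")
    if not np.isfinite(x.to_numpy()).all():
        raise DataError("non-finite relative values (zero non-stress value?)")
    return x


@dataclass
class MembershipResult:
    """Membership indices for one trait."""

    X: pd.DataFrame  # accession x replication relative values
    check_tolerant_mean: pd.Series  # X_kT per replication
    check_sensitive_mean: pd.Series  # X_kS per replication
    M: pd.DataFrame  # accession x replication membership index
    accession_mean: pd.Series  # the indicator value (MPW or MPH)


def membership_index(
    X: pd.DataFrame,
    tolerant_ids: list[str],
    sensitive_ids: list[str],
    min_replications: int = 2,
) -> MembershipResult:
    """Per-replication affine rescaling of X anchored at the check means."""
    for name, ids in (("tolerant", tolerant_ids), ("sensitive", sensitive_ids)):
        unknown = set(ids) - set(X.index)
        if unknown:
            raise DataError(f"unknown {name} check accessions: {sorted(unknown)}")
        if not ids:
            raise DataError(f"no {name} check accessions supplied")
    x_t = X.loc[tolerant_ids].mean(axis=0)
    x_s = X.loc[sensitive_ids].mean(axis=0)
    degenerate = (x_t - x_s).abs() < 1e-12
    if degenerate.any():
        ks = list(X.columns[degenerate])
        raise DegenerateCheckError(
            f"tolerant and sensitive check means coincide in replication(s) {ks}"
        )
    M = (X - x_s) / (x_t - x_s)
    n_obs = M.notna().sum(axis=1)
    if (n_obs < min_replications).any():
        short = list(M.index[n_obs < min_replications])
        raise DataError(
            f"accessions with fewer than {min_replications} replications: "
            f"{short[:10]}"
        )
    return MembershipResult(
        X=X,
        check_tolerant_mean=x_t,
        check_sensitive_mean=x_s,
        M=M,
        accession_mean=M.mean(axis=1).rename("indicator"),
    )


@dataclass
class HeritabilityEstimate:
    sigma2_g: float
    sigma2_e: float
    r: float
    h2: float


def anova_heritability(M: pd.DataFrame) -> HeritabilityEstimate:
    """One-way random-effects ANOVA over replications.

    s2_g = max(0, (MS_accession - MS_error) / r), s2_e = MS_error, and
    h2 = s2_g / (s2_g + s2_e / r) clamped to [0, 1].  For near-balanced
    data r is the effective group size n0 = (N - sum(n_i^2)/N)/(a - 1).
    """
    values = M.to_numpy(dtype=float)
    a = values.shape[0]
    if a < 2:
        raise DataError("heritability needs at least 2 accessions")
    n_i = np.isfinite(values).sum(axis=1)
    if (n_i < 2).any():
        raise DataError("heritability needs at least 2 replications per accession")
    N = int(n_i.sum())
    means = np.nanmean(values, axis=1)
    grand = np.nansum(values) / N
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(np.nansum((values - means[:, None]) ** 2))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a) if N > a else 0.0
    r_eff = (N - float(np.sum(n_i**2)) / N) / (a - 1)
    sigma2_g = max(0.0, (ms_between - ms_within) / r_eff)
    sigma2_e = ms_within
    denom = sigma2_g + sigma2_e / r_eff
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return HeritabilityEstimate(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        r=float(r_eff),
        h2=float(min(max(h2, 0.0), 1.0)),
    )


@dataclass
class IndicatorSummary:
    per_subpop: pd.DataFrame  # rows: subpop + ALL; cols: n, mean, min, max, range
    correlation: float
    correlation_p: float
    top: list[str]
    bottom: list[str]


def summarize_indicators(
    mpw: pd.Series,
    mph: pd.Series,
    subpop: pd.Series | None = None,
    n_extreme: int = 12,
) -> IndicatorSummary:
    """Distribution summary, Pearson correlation of the two indicators, and
    the extreme (most tolerant / most sensitive) accessions by mean rank."""
    shared = mpw.index.intersection(mph.index)
    if len(shared) == 0:
        raise DataError("indicator series share no accessions")
    mpw, mph = mpw.loc[shared], mph.loc[shared]
    if subpop is None:
        subpop = pd.Series("ALL", index=shared)
    frames = []
    both = pd.DataFrame({"MPW": mpw, "MPH": mph, "subpop": subpop.loc[shared]})
    groups = [("ALL", both)] + [
        (str(lab), grp) for lab, grp in both.groupby("subpop", sort=True)
    ]
    for label, grp in groups:
        for ind in ("MPW", "MPH"):
            v = grp[ind]
            frames.append(
                {
                    "group": label,
                    "indicator": ind,
                    "n": len(v),
                    "mean": v.mean(),
                    "min": v.min(),
                    "max": v.max(),
                    "range": v.max() - v.min(),
                }
            )
    if len(shared) >= 3 and mpw.std() > 0 and mph.std() > 0:
        corr, p = stats.pearsonr(mpw, mph)
    else:
        corr, p = (1.0 if mpw.equals(mph) else np.nan), np.nan
    score = (mpw.rank() + mph.rank()) / 2
    order = score.sort_values().index
    n_extreme = min(n_extreme, len(shared))
    return IndicatorSummary(
        per_subpop=pd.DataFrame(frames),
        correlation=float(corr),
        correlation_p=float(p) if np.isfinite(p) else float("nan"),
        top=list(order[-n_extreme:][::-1]),
        bottom=list(order[:n_extreme]),
    )
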