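"""Synthetic germplasm panels with LD-block structure, multi-allele QTL
effects, and replicated two-regime (stress / non-stress) trial data.

The generator emulates an inbred, self-pollinated panel: every genotype is
fully homozygous, so a genotype column IS a haplotype.  SNPs come in
contiguous blocks whose columns are drawn from a per-block pool of 2-12
haplotypes; two (or more) subpopulations share the pools but drift in pool
frequencies.  Stress/non-stress trait values are built so that the
per-replication stress ratio is linear in an additive multi-allele QTL
genotypic value, with Gaussian noise calibrated to hit a target broad-sense
heritability on the replication-mean basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError
from .snpldb import ALT_HOM, GenotypeMatrix, LDBlock, Marker, MarkerSet, REF_HOM

TRAITS = ("plant_weight", "plant_height")
_TRAIT_BASELINE = {"plant_weight": 15.0, "plant_height": 80.0}


@dataclass
class SimConfig:
    """Design of a synthetic panel and its stress trial.

    ``haplotypes_per_block`` may be a single integer or an inclusive
    (low, high) range sampled per block.  ``drift_concentration`` gives the
    Dirichlet concentration of haplotype-pool frequencies for each
    subpopulation; smaller values produce more skewed (drifted) pools.
    """

    n_accessions: int
    n_subpops: int = 2
    subpop_proportions: tuple[float, ...] | None = None
    n_chromosomes: int = 20
    snps_per_chromosome: int = 150
    block_length_bp: int = 10_000
    snps_per_block: int = 5
    block_gap_bp: int = 40_000
    haplotypes_per_block: int | tuple[int, int] = (2, 6)
    min_hap_freq: float = 0.02
    drift_concentration: tuple[float, ...] = (0.5, 2.0)
    private_allele_rate: float = 0.10
    n_qtl: int = 15
    effect_sd: float = 0.15
    qtl_intercept: float = 0.55
    subpop_shift: tuple[float, ...] | None = None
    target_h2: float = 0.80
    n_replications: int = 5
    n_checks_tolerant: int = 5
    n_checks_sensitive: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1:
            raise ConfigError("n_accessions must be positive")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops must be positive")
        if self.subpop_proportions is None:
            self.subpop_proportions = tuple(
                [1.0 / self.n_subpops] * self.n_subpops
            )
        if len(self.subpop_proportions) != self.n_subpops:
            raise ConfigError(
                "subpop_proportions length must equal n_subpops"
            )
        if abs(sum(self.subpop_proportions) - 1.0) > 1e-9:
            raise ConfigError("subpop_proportions must sum to 1")
        for name in (
            "n_chromosomes",
            "snps_per_chromosome",
            "block_length_bp",
            "snps_per_block",
            "block_gap_bp",
            "n_replications",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        hap = self.haplotypes_per_block
        lo, hi = (hap, hap) if isinstance(hap, int) else hap
        if lo < 1 or hi > 12 or lo > hi:
            raise ConfigError(
                "haplotypes_per_block must lie within [1, 12]"
            )
        self._hap_range = (lo, hi)
        if hi > 2 ** self.snps_per_block:
            raise ConfigError(
                "haplotypes_per_block exceeds 2**snps_per_block distinct "
                "haplotypes"
            )
        if self.n_qtl < 0:
            raise ConfigError("n_qtl must be >= 0")
        if self.effect_sd <= 0:
            raise ConfigError("effect_sd must be positive")
        if not (0.0 < self.target_h2 <= 1.0):
            raise ConfigError("target_h2 must lie in (0, 1]")
        if not (0.0 <= self.min_hap_freq < 0.5):
            raise ConfigError("min_hap_freq must lie in [0, 0.5)")
        if not (0.0 <= self.private_allele_rate <= 1.0):
            raise ConfigError("private_allele_rate must lie in [0, 1]")
        if self.n_checks_tolerant < 1 or self.n_checks_sensitive < 1:
            raise ConfigError("check counts must be positive")
        if (
            self.n_checks_tolerant + self.n_checks_sensitive
            > self.n_accessions
        ):
            raise ConfigError("more checks than accessions")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_hap_range", None)
        return d


@dataclass
class Panel:
    """A synthetic panel plus the ground truth used to build it."""

    genotypes: GenotypeMatrix
    subpop: pd.Series  # accession -> subpopulation label
    true_blocks: list[LDBlock]
    block_haplotypes: list[np.ndarray]  # per block: (k, m) 0/1 pool
    block_assign: np.ndarray  # (n_blocks, n_accessions) haplotype index
    pool_freqs: list[np.ndarray]  # per block: (n_subpops, k) frequencies

    @property
    def accessions(self) -> list[str]:
        return self.genotypes.accessions


@dataclass
class TrueQTLModel:
    """Ground-truth additive multi-allele QTL model over panel blocks."""

    qtl_blocks: list[int]  # indices into panel.true_blocks
    allele_effects: list[np.ndarray]  # per QTL: effect per pool haplotype
    intercept: float
    subpop_shift: dict[str, float]

    def genotypic_values(self, panel: Panel) -> pd.Series:
        g = np.full(len(panel.accessions), self.intercept)
        for bi, eff in zip(self.qtl_blocks, self.allele_effects):
            g += eff[panel.block_assign[bi]]
        g += panel.subpop.map(self.subpop_shift).to_numpy()
        return pd.Series(g, index=panel.accessions, name="genotypic_value")


@dataclass
class SimulatedTrial:
    """Tidy replicated two-regime trial measurements with check rosters."""

    data: pd.DataFrame  # accession, replication, regime, trait, value
    tolerant_checks: list[str]
    sensitive_checks: list[str]
    true_values: dict[str, pd.Series]  # per trait genotypic ratio values


def _subpop_labels(n: int) -> list[str]:
    if n == 2:
        return ["LR", "RC"]
    return [f"P{i + 1}" for i in range(n)]


def _draw_block_pool(rng: np.random.Generator, k: int, m: int) -> np.ndarray:
    """k distinct haplotypes of length m, each SNP polymorphic if k >= 2."""
    for _ in range(200):
        pool = rng.integers(0, 2, size=(k, m))
        if k >= 2:
            for col in range(m):
                if len(np.unique(pool[:, col])) == 1:
                    pool[rng.integers(0, k), col] ^= 1
        if len({tuple(r) for r in pool}) == k:
            return pool
    raise GenerationError(
        f"could not draw {k} distinct haplotypes of length {m}"
    )


def _draw_pool_freqs(
    rng: np.random.Generator, k: int, conc: list[float], config: SimConfig
) -> np.ndarray:
    """Per-subpopulation haplotype-pool frequencies: floored Dirichlet draws,
    then occasional subpopulation-private alleles (a haplotype zeroed out in
    one subpopulation but kept in the others), emulating allele exclusion
    and emergence between landraces and released cultivars."""
    n_sub = config.n_subpops
    freqs = np.empty((n_sub, k))
    for s in range(n_sub):
        raw = rng.dirichlet(np.full(k, conc[s]))
        freqs[s] = (1 - k * config.min_hap_freq) * raw + config.min_hap_freq
    if n_sub >= 2 and k >= 2 and config.private_allele_rate > 0:
        for s in range(n_sub):
            if rng.random() >= config.private_allele_rate:
                continue
            h = int(rng.integers(k))
            others = [t for t in range(n_sub) if t != s]
            if (freqs[s] > 0).sum() >= 2 and any(
                freqs[t][h] > 0 for t in others
            ):
                freqs[s, h] = 0.0
                freqs[s] /= freqs[s].sum()
    return freqs


def simulate_founder_genotypes(config: SimConfig) -> Panel:
    """Generate the inbred panel: homozygous SNP calls in LD blocks with
    subpopulation-drifted haplotype-pool frequencies."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_accessions
    props = np.asarray(config.subpop_proportions)
    counts = np.floor(props * n).astype(int)
    counts[0] += n - counts.sum()
    labels = _subpop_labels(config.n_subpops)
    subpop = np.repeat(labels, counts)
    accessions = [f"ACC{i + 1:04d}" for i in range(n)]
    sub_idx = np.repeat(np.arange(config.n_subpops), counts)

    conc = list(config.drift_concentration)
    conc = [conc[s % len(conc)] for s in range(config.n_subpops)]

    chrom_names = [f"Chr{c + 1:02d}" for c in range(config.n_chromosomes)]
    lo, hi = config._hap_range
    m = config.snps_per_block
    spacing = max(config.block_length_bp // max(m - 1, 1), 1)

    rows = []
    call_rows = []
    true_blocks: list[LDBlock] = []
    block_haps: list[np.ndarray] = []
    assigns = []
    pool_freqs_all: list[np.ndarray] = []
    bases = np.array(list("ACGT"))
    for chrom in chrom_names:
        n_blocks = config.snps_per_chromosome // m
        n_single = config.snps_per_chromosome - n_blocks * m
        pos = 1
        snp_row = len(rows)
        for _ in range(n_blocks):
            k = int(rng.integers(lo, hi + 1))
            pool = _draw_block_pool(rng, k, m)
            freqs = _draw_pool_freqs(rng, k, conc, config)
            assign = np.empty(n, dtype=np.int16)
            for s in range(config.n_subpops):
                mask = sub_idx == s
                assign[mask] = rng.choice(k, size=mask.sum(), p=freqs[s])
            block_calls = np.where(pool[assign].T == 1, ALT_HOM, REF_HOM)
            positions = [pos + j * spacing for j in range(m)]
            for j in range(m):
                ref, alt = rng.choice(4, size=2, replace=False)
                rows.append((chrom, positions[j], bases[ref], bases[alt]))
                call_rows.append(block_calls[j].astype(np.int8))
            true_blocks.append(
                LDBlock(
                    chrom,
                    tuple(range(snp_row, snp_row + m)),
                    positions[0],
                    positions[-1],
                )
            )
            block_haps.append(pool)
            assigns.append(assign)
            pool_freqs_all.append(freqs)
            snp_row += m
            pos = positions[-1] + config.block_gap_bp
        for _ in range(n_single):
            k = min(2, hi) if lo >= 2 or hi >= 2 else 1
            freqs = _draw_pool_freqs(rng, k, conc, config)
            assign = np.empty(n, dtype=np.int16)
            for s in range(config.n_subpops):
                mask = sub_idx == s
                assign[mask] = rng.choice(k, size=mask.sum(), p=freqs[s])
            calls = np.where(assign == 1, ALT_HOM, REF_HOM).astype(np.int8)
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((chrom, pos, bases[ref], bases[alt]))
            call_rows.append(calls)
            pos += config.block_gap_bp

    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    gm = GenotypeMatrix(accessions, snps, np.stack(call_rows))
    return Panel(
        genotypes=gm,
        subpop=pd.Series(subpop, index=accessions, name="subpop"),
        true_blocks=true_blocks,
        block_haplotypes=block_haps,
        block_assign=np.stack(assigns) if assigns else np.empty((0, n), int),
        pool_freqs=pool_freqs_all,
    )


def inject_noise(
    panel: Panel,
    missing_rate: float = 0.0,
    het_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Return a copy of the panel genotypes with uniform missing/het calls
    injected, for QC and imputation tests."""
    from .snpldb import HET, MISSING

    rng = np.random.default_rng([seed, 99])
    gm = panel.genotypes.copy()
    u = rng.random(gm.calls.shape)
    gm.calls[u < missing_rate] = MISSING
    gm.calls[(u >= missing_rate) & (u < missing_rate + het_rate)] = HET
    return gm


def assign_qtl_effects(panel: Panel, config: SimConfig) -> TrueQTLModel:
    """Pick ``n_qtl`` polymorphic blocks and draw centered per-allele effects."""
    rng = np.random.default_rng([config.seed, 1])
    poly = [
        i
        for i, assign in enumerate(panel.block_assign)
        if len(np.unique(assign)) >= 2
    ]
    if config.n_qtl > len(poly):
        raise GenerationError(
            f"requested {config.n_qtl} QTL but only {len(poly)} polymorphic "
            "blocks are available"
        )
    chosen = sorted(rng.choice(poly, size=config.n_qtl, replace=False))
    effects = []
    for bi in chosen:
        k = panel.block_haplotypes[bi].shape[0]
        e = rng.normal(0.0, config.effect_sd, size=k)
        effects.append(e - e.mean())
    labels = sorted(panel.subpop.unique())
    shift = config.subpop_shift or tuple([0.0] * len(labels))
    return TrueQTLModel(
        qtl_blocks=[int(b) for b in chosen],
        allele_effects=effects,
        intercept=config.qtl_intercept,
        subpop_shift={lab: float(s) for lab, s in zip(labels, shift)},
    )


def residual_sd_for_h2(
    sigma2_g: float,
    target_h2: float,
    r: int,
    n_checks_tolerant: int | None = None,
    n_checks_sensitive: int | None = None,
) -> float:
    """Per-observation noise SD giving mean-basis heritability target_h2.

    From h2 = s2g / (s2g + s2e / r):  s2e = r * s2g * (1 - h2) / h2.

    When check counts are given, s2e is deflated by (1 + 1/n_T + 1/n_S):
    the membership transform subtracts the per-replication sensitive-check
    mean and divides by the check-mean difference, so the noise of the
    check means re-enters every index value as a shared per-replication
    shift that a one-way ANOVA counts as error.  To first order that
    inflates the effective error variance by exactly this factor.
    """
    s2e = r * sigma2_g * (1.0 - target_h2) / target_h2
    if n_checks_tolerant and n_checks_sensitive:
        s2e /= 1.0 + 1.0 / n_checks_tolerant + 1.0 / n_checks_sensitive
    return float(np.sqrt(s2e))


def simulate_drought_trial(
    panel: Panel,
    model: TrueQTLModel | dict[str, TrueQTLModel],
    config: SimConfig,
) -> SimulatedTrial:
    """Replicated stress / non-stress trait values on the panel.

    Non-stress values are a trait baseline times a per-replication effect
    times lognormal noise.  Stress values are the non-stress value times a
    ratio equal to the accession's genotypic value plus Gaussian noise,
    with the noise SD calibrated so the membership index computed
    downstream has heritability ~ target_h2 on the replication-mean basis.
    The tolerant (sensitive) checks are the accessions with the highest
    (lowest) mean genotypic value.
    """
    rng = np.random.default_rng([config.seed, 2])
    models = model if isinstance(model, dict) else {t: model for t in TRAITS}
    g = {t: models[t].genotypic_values(panel) for t in models}
    r = config.n_replications

    # checks: extremes of the standardized mean genotypic value
    g_std = sum(
        (gv - gv.mean()) / (gv.std(ddof=0) or 1.0) for gv in g.values()
    ) / len(g)
    order = g_std.sort_values().index
    sensitive = list(order[: config.n_checks_sensitive])
    tolerant = list(order[-config.n_checks_tolerant:])

    records = []
    for trait, gv in g.items():
        s2g = float(gv.var(ddof=0))
        sd_e = (
            residual_sd_for_h2(
                s2g, config.target_h2, r,
                config.n_checks_tolerant, config.n_checks_sensitive,
            )
            if s2g > 0
            else 0.0
        )
        base = _TRAIT_BASELINE.get(trait, 10.0)
        rep_effect = np.exp(rng.normal(0.0, 0.05, size=r))
        for k in range(r):
            nonstress = base * rep_effect[k] * np.exp(
                rng.normal(0.0, 0.05, size=len(gv))
            )
            ratio = gv.to_numpy() + rng.normal(0.0, sd_e, size=len(gv))
            ratio = np.maximum(ratio, 0.01)
            stress = nonstress * ratio
            for acc, vn, vs in zip(gv.index, nonstress, stress):
                records.append((acc, k + 1, "nonstress", trait, vn))
                records.append((acc, k + 1, "stress", trait, vs))
    data = pd.DataFrame(
        records, columns=["accession", "replication", "regime", "trait", "value"]
    )
    return SimulatedTrial(
        data=data,
        tolerant_checks=tolerant,
        sensitive_checks=sensitive,
        true_values=g,
    )


def markers_from_true_blocks(panel: Panel) -> MarkerSet:
    """Encode the generator's own blocks directly as SNPLDB markers.

    Bypasses LD-block detection; used when a test or analysis targets the
    association machinery rather than block discovery.
    """
    from .snpldb import build_snpldb_markers

    return build_snpldb_markers(panel.genotypes, panel.true_blocks)


def simulate_study(
    config: SimConfig,
) -> tuple[Panel, dict[str, TrueQTLModel], SimulatedTrial]:
    """Convenience wrapper: panel, one QTL model per trait, and the trial."""
    panel = simulate_founder_genotypes(config)
    rng = np.random.default_rng([config.seed, 3])
    models = {}
    for j, trait in enumerate(TRAITS):
        sub = SimConfig(**{**config.to_dict(), "seed": int(rng.integers(2**31))})
        models[trait] = assign_qtl_effects(panel, sub)
    trial = simulate_drought_trial(panel, models, config)
    return panel, models, trial
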