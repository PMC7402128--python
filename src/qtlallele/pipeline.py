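"""End-to-end orchestration: phenotype -> markers -> structure -> GWAS ->
QTL-allele matrix -> subpopulation differentiation -> cross prediction.

Every output table carries a header with the package version, a hash of
the run configuration, and the master seed; stage logs record the counts
a reader needs to audit the run (SNPs kept, blocks, markers, preselected
and selected loci, total R^2, crosses flagged).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .allele_matrix import (
    QTLAlleleMatrix,
    allele_turnover,
    build_matrix,
    subpop_differentiation,
)
from .association import StepwiseModel, locus_contribution, stage1_scan, stage2_stepwise
from .crosses import CrossRanking, predict_crosses
from .errors import ConfigError, DataError
from .phenotype import (
    anova_heritability,
    membership_index,
    relative_trait,
    summarize_indicators,
)
from .similarity import genetic_similarity, top_eigenvectors
from .simulate import SimConfig, TRAITS, simulate_study
from .snpldb import build_snpldb_markers, find_ld_blocks, impute_missing, qc_filter_snps

logger = logging.getLogger("qtlallele")

INDICATOR_OF = {"plant_weight": "MPW", "plant_height": "MPH"}


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Either ``sim`` (a synthetic-panel design) or the real-input paths
    (``genotypes_path``, ``trial_path``, ``checks_path``,
    ``subpop_path``) must be provided.
    """

    sim: SimConfig | None = None
    genotypes_path: str | None = None
    genotypes_format: str | None = None
    trial_path: str | None = None
    checks_path: str | None = None
    subpop_path: str | None = None
    # QC / blocks
    max_missing_het: float = 0.30
    min_maf: float = 0.01
    block_max_dist: int = 200_000
    rare_allele_floor: float = 0.01
    # structure / association
    k_eigenvectors: int = 10
    alpha_stage1: float = 0.05
    alpha_entry: float = 0.01
    alpha_stay: float = 0.01
    min_carriers: int = 3
    # crosses
    n_progeny: int = 10_000
    percentile_q: float = 95.0
    criterion: str = "exceeds_population_max"
    max_crosses: int | None = None
    n_extreme: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and self.genotypes_path is None:
            raise ConfigError(
                "RunConfig needs either a SimConfig or real-input paths"
            )
        for name, lo, hi in (
            ("max_missing_het", 0.0, 1.0),
            ("min_maf", 0.0, 0.5),
            ("rare_allele_floor", 0.0, 0.5),
            ("alpha_stage1", 0.0, 1.0),
            ("alpha_entry", 0.0, 1.0),
            ("alpha_stay", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    indicators: pd.DataFrame  # accession, MPW, MPH, subpop
    heritability: dict[str, float]
    markers: object
    models: dict[str, StepwiseModel]
    matrices: dict[str, QTLAlleleMatrix]
    differentiation: dict[str, object]
    turnover: dict[str, object]
    crosses: CrossRanking | None
    counts: dict = field(default_factory=dict)


def _stage_seed(master: int, stage: int) -> int:
    """Derive a per-stage seed from the master seed (stable, re-runnable)."""
    return int(
        np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31)
    )


def run_pipeline(config: RunConfig, outdir: str | Path | None = None
                 ) -> PipelineResult:
    out = Path(outdir) if outdir is not None else None
    meta = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
    }
    counts: dict = {}

    # ---- inputs -----------------------------------------------------------
    if config.sim is not None:
        sim = SimConfig(**{**config.sim.to_dict(), "seed": config.seed})
        panel, true_models, trial = simulate_study(sim)
        gm_raw = panel.genotypes
        trial_data = trial.data
        tolerant, sensitive = trial.tolerant_checks, trial.sensitive_checks
        subpop = panel.subpop
        if out is not None:
            io.write_genotypes_vcf(gm_raw, out / "panel.vcf")
            io.write_genotypes_tsv(gm_raw, out / "panel.tsv", meta)
            io.write_trial_csv(trial_data, out / "trial.csv")
            io.write_checks(tolerant, sensitive, out / "checks.tsv")
            truth_rows = []
            for trait, model in true_models.items():
                for bi, eff in zip(model.qtl_blocks, model.allele_effects):
                    for a, e in enumerate(eff):
                        truth_rows.append(
                            {"trait": trait, "block": bi, "allele": a, "effect": e}
                        )
            io.write_table(pd.DataFrame(truth_rows), out / "truth.tsv", meta)
    else:
        gm_raw = io.read_genotypes(config.genotypes_path, config.genotypes_format)
        trial_data = io.read_trial_csv(config.trial_path)
        tolerant, sensitive = io.read_checks(config.checks_path)
        if config.subpop_path:
            sp = io.read_table(config.subpop_path)
            subpop = pd.Series(
                sp["subpop"].to_numpy(), index=sp["accession"], name="subpop"
            )
        else:
            subpop = pd.Series(
                "ALL", index=gm_raw.accessions, name="subpop"
            )

    # ---- phenotype --------------------------------------------------------
    indicators = {}
    h2 = {}
    for trait in TRAITS:
        X = relative_trait(trial_data, trait)
        res = membership_index(X, tolerant, sensitive)
        est = anova_heritability(res.M)
        name = INDICATOR_OF[trait]
        indicators[name] = res.accession_mean
        h2[name] = est.h2
        logger.info("%s: h2=%.3f (s2g=%.4f, s2e=%.4f)", name, est.h2,
                    est.sigma2_g, est.sigma2_e)
    ind_table = pd.DataFrame(indicators)
    ind_table["subpop"] = subpop.loc[ind_table.index]
    summary = summarize_indicators(
        ind_table["MPW"], ind_table["MPH"], subpop, config.n_extreme
    )
    counts["h2"] = h2
    counts["indicator_correlation"] = summary.correlation

    # ---- markers ----------------------------------------------------------
    gm, qc_report = qc_filter_snps(
        gm_raw, config.max_missing_het, config.min_maf
    )
    counts["qc"] = qc_report
    if gm.n_snps == 0:
        raise DataError("stage snpldb: no SNPs left after QC")
    gm, imputed_frac = impute_missing(gm)
    counts["imputed_fraction"] = imputed_frac
    blocks = find_ld_blocks(gm, max_dist=config.block_max_dist,
                            min_maf=config.min_maf)
    markers = build_snpldb_markers(gm, blocks, config.rare_allele_floor)
    counts["n_snps_kept"] = gm.n_snps
    counts["n_blocks"] = len(blocks)
    counts["n_markers"] = len(markers)
    logger.info("markers: %d SNPs -> %d blocks -> %d SNPLDB markers",
                gm.n_snps, len(blocks), len(markers))

    # ---- structure --------------------------------------------------------
    sim_matrix = genetic_similarity(markers)
    k = min(config.k_eigenvectors, len(markers.accessions) - 1)
    basis = top_eigenvectors(sim_matrix, k)

    # ---- association ------------------------------------------------------
    models: dict[str, StepwiseModel] = {}
    matrices: dict[str, QTLAlleleMatrix] = {}
    for name in ("MPW", "MPH"):
        y = ind_table[name]
        y = y.loc[markers.accessions]
        scan = stage1_scan(markers, y, basis, config.alpha_stage1,
                           config.min_carriers)
        model = stage2_stepwise(
            markers, scan.preselected, y, basis,
            h2_cap=h2[name],
            alpha_entry=config.alpha_entry,
            alpha_stay=config.alpha_stay,
            min_carriers=config.min_carriers,
        )
        models[name] = model
        matrices[name] = build_matrix(model, markers, subpop)
        counts[f"{name}_preselected"] = len(scan.preselected)
        counts[f"{name}_selected"] = len(model.loci)
        counts[f"{name}_total_r2"] = model.total_r2
        logger.info("%s: %d preselected, %d selected, R2=%.3f (cap %.3f)",
                    name, len(scan.preselected), len(model.loci),
                    model.total_r2, model.h2_cap)
        if out is not None:
            io.write_table(scan.table, out / f"scan_{name}.tsv", meta)
            io.write_model(model, out / f"model_{name}.tsv", meta)
            io.write_table(
                locus_contribution(model), out / f"qtl_{name}.tsv", meta
            )

    # ---- differentiation --------------------------------------------------
    differentiation = {}
    turnover = {}
    if subpop.nunique() >= 2:
        labels = sorted(subpop.unique())
        for name, mat in matrices.items():
            comp = subpop_differentiation(mat)
            differentiation[name] = comp
            turnover[name] = allele_turnover(mat, labels[0], labels[1])
            counts[f"{name}_differentiated"] = comp.n_significant
            if out is not None:
                io.write_table(comp.table, out / f"diff_{name}.tsv", meta)

    # ---- crosses ----------------------------------------------------------
    ranking = None
    if len(matrices) == 2:
        crosses_iter = None
        if config.max_crosses is not None:
            from itertools import islice

            from .crosses import enumerate_crosses

            crosses_iter = list(islice(
                enumerate_crosses(markers.accessions), config.max_crosses
            ))
        ranking = predict_crosses(
            {n: matrices[n] for n in ("MPW", "MPH")},
            crosses=crosses_iter,
            observed={n: ind_table[n] for n in ("MPW", "MPH")},
            n_progeny=config.n_progeny,
            q=config.percentile_q,
            criterion=config.criterion,
            seed=_stage_seed(config.seed, 7),
            weights={"MPW": h2["MPW"], "MPH": h2["MPH"]},
        )
        counts["n_crosses"] = len(ranking.table)
        counts["n_optimal"] = int(ranking.table["optimal"].sum())
        logger.info("crosses: %d simulated, %d optimal (%s)",
                    counts["n_crosses"], counts["n_optimal"], config.criterion)

    # ---- outputs ----------------------------------------------------------
    if out is not None:
        io.write_table(
            ind_table.reset_index(names="accession"),
            out / "indicators.tsv", meta,
        )
        io.write_table(summary.per_subpop, out / "indicator_summary.tsv", meta)
        io.write_markers(markers, out, meta)
        for name, mat in matrices.items():
            cells = mat.alleles.astype(str) + ":" + mat.effects.round(4).astype(str)
            cells.index.name = "accession"
            io.write_table(cells, out / f"matrix_{name}.tsv", meta, index=True)
        if ranking is not None:
            io.write_table(
                ranking.table, out / "crosses.tsv",
                {**meta, "criterion": ranking.criterion, "q": ranking.q,
                 "n_progeny": ranking.n_progeny},
            )
        io.write_table(
            pd.DataFrame([{"key": k, "value": json.dumps(v, default=str)}
                          for k, v in counts.items()]),
            out / "run_counts.tsv", meta,
        )

    return PipelineResult(
        config=config,
        indicators=ind_table,
        heritability=h2,
        markers=markers,
        models=models,
        matrices=matrices,
        differentiation=differentiation,
        turnover=turnover,
        crosses=ranking,
        counts=counts,
    )
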