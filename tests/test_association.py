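"""Two-stage multi-locus multi-allele association scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qtlallele.association import (
    estimate_allele_effects,
    locus_contribution,
    stage1_scan,
    stage2_stepwise,
)
from qtlallele.simulate import (
    SimConfig,
    assign_qtl_effects,
    markers_from_true_blocks,
    simulate_founder_genotypes,
)
from qtlallele.snpldb import Marker, MarkerSet

from conftest import small_config


def _marker_set_from_codes(code_rows, n_acc):
    markers = [
        Marker(
            id=f"M{i}", chrom="Chr01", start=1000 * (i + 1), end=1000 * (i + 1),
            snp_indices=(i,),
            alleles=[str(a) for a in range(int(max(codes)) + 1)],
            codes=np.asarray(codes, dtype=np.int16),
        )
        for i, codes in enumerate(code_rows)
    ]
    return MarkerSet([f"s{j}" for j in range(n_acc)], markers)


def _phen(values, ms):
    return pd.Series(np.asarray(values, dtype=float), index=ms.accessions)


class TestStage1:
    def test_null_preselection_rate_near_alpha(self):
        rng = np.random.default_rng(12)
        n, m = 200, 2000
        codes = rng.integers(0, 2, size=(m, n))
        ms = _marker_set_from_codes(codes, n)
        y = _phen(rng.normal(size=n), ms)
        res = stage1_scan(ms, y, covariates=None, alpha=0.05)
        rate = len(res.preselected) / len(res.table)
        # binomial 99% band around 0.05 at m = 2000
        sd = np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) < 2.58 * sd + 1e-12

    def test_perfect_association_has_smallest_p(self):
        rng = np.random.default_rng(3)
        n = 80
        codes = rng.integers(0, 3, size=(30, n))
        ms = _marker_set_from_codes(codes, n)
        means = np.array([0.0, 1.0, 2.5])
        y = _phen(means[codes[7]], ms)
        res = stage1_scan(ms, y)
        best = res.table.loc[res.table["p"].idxmin(), "marker"]
        assert best == "M7"

    def test_f_statistic_matches_linear_model_oracle(self):
        """Partial F of the marker term equals the ANCOVA F from an
        independently fitted OLS (statsmodels)."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(8)
        n = 30
        codes = rng.integers(0, 3, size=(1, n))
        ms = _marker_set_from_codes(codes, n)
        cov = rng.normal(size=(n, 2))
        y = 0.5 * codes[0] + cov @ [0.3, -0.2] + rng.normal(0, 0.5, n)
        res = stage1_scan(ms, _phen(y, ms), covariates=cov, min_carriers=1)
        df = pd.DataFrame(
            {"y": y, "g": codes[0].astype(str), "c1": cov[:, 0], "c2": cov[:, 1]}
        )
        full = smf.ols("y ~ c1 + c2 + C(g)", df).fit()
        reduced = smf.ols("y ~ c1 + c2", df).fit()
        tab = anova_lm(reduced, full)
        assert res.table["F"].iloc[0] == pytest.approx(tab["F"].iloc[1], rel=1e-6)
        assert res.table["p"].iloc[0] == pytest.approx(
            tab["Pr(>F)"].iloc[1], rel=1e-6
        )

    def test_marker_below_min_carriers_skipped(self):
        codes = np.array([[0] * 18 + [1, 1]])
        ms = _marker_set_from_codes(codes, 20)
        res = stage1_scan(ms, _phen(np.arange(20.0), ms), min_carriers=3)
        assert res.skipped == ["M0"]
        assert len(res.table) == 0


class TestStage2:
    def test_zero_cap_selects_nothing(self):
        rng = np.random.default_rng(1)
        n = 60
        codes = rng.integers(0, 2, size=(5, n))
        ms = _marker_set_from_codes(codes, n)
        y = _phen(codes[0] * 2.0 + rng.normal(0, 0.1, n), ms)
        model = stage2_stepwise(ms, [m.id for m in ms], y, h2_cap=0.0)
        assert model.loci == []
        assert model.total_r2 == 0.0
        assert model.unmapped_share == 0.0

    def test_matches_exhaustive_best_subset_of_two(self):
        """With two strong QTL among six candidates, the first two stepwise
        picks equal the best RSS pair found by exhaustive search."""
        for seed in range(4):
            rng = np.random.default_rng(seed)
            n = 120
            codes = rng.integers(0, 3, size=(6, n))
            ms = _marker_set_from_codes(codes, n)
            eff = np.array([0.0, 1.2, -0.8])
            y_vals = eff[codes[1]] + eff[codes[4]] + rng.normal(0, 0.4, n)
            y = _phen(y_vals, ms)
            model = stage2_stepwise(ms, [m.id for m in ms], y, h2_cap=1.0)

            def rss_of(pair):
                cols = [np.ones(n)]
                for mid in pair:
                    c = ms.by_id(mid).codes
                    for a in range(1, c.max() + 1):
                        cols.append((c == a).astype(float))
                X = np.column_stack(cols)
                beta, *_ = np.linalg.lstsq(X, y_vals, rcond=None)
                return ((y_vals - X @ beta) ** 2).sum()

            best_pair = min(
                itertools.combinations([m.id for m in ms], 2), key=rss_of
            )
            assert set(model.loci[:2]) == set(best_pair)

    def test_total_r2_never_exceeds_cap(self):
        rng = np.random.default_rng(5)
        n = 100
        codes = rng.integers(0, 3, size=(12, n))
        ms = _marker_set_from_codes(codes, n)
        strong = sum(
            np.array([0.0, 1.0, -1.0])[codes[i]] for i in range(6)
        )
        y = _phen(strong + rng.normal(0, 0.3, n), ms)
        for cap in (0.1, 0.3, 0.5, 0.9):
            model = stage2_stepwise(ms, [m.id for m in ms], y, h2_cap=cap)
            assert model.total_r2 <= cap + 1e-9

    def test_accession_permutation_invariance(self, study, true_markers,
                                              fitted_model):
        model, y, basis, h2 = fitted_model
        perm = np.random.default_rng(0).permutation(len(true_markers.accessions))
        acc = [true_markers.accessions[i] for i in perm]
        permuted = MarkerSet(
            acc,
            [
                Marker(m.id, m.chrom, m.start, m.end, m.snp_indices,
                       m.alleles, m.codes[perm])
                for m in true_markers
            ],
        )
        scan_a = stage1_scan(true_markers, y, basis.vectors)
        scan_b = stage1_scan(permuted, y.loc[acc], basis.vectors[perm])
        merged = scan_a.table.merge(scan_b.table, on="marker")
        np.testing.assert_allclose(
            merged["F_x"], merged["F_y"], rtol=1e-8, atol=1e-10
        )

    def test_recovers_large_effect_qtl(self):
        """Most of the largest-effect simulated QTL are found (within one
        block) on a noise-calibrated panel."""
        hits, total = 0, 0
        for seed in range(3):
            cfg = small_config(
                n_accessions=400, n_chromosomes=4, snps_per_chromosome=50,
                n_qtl=20, seed=seed, target_h2=0.8, effect_sd=0.15,
            )
            panel = simulate_founder_genotypes(cfg)
            model_true = assign_qtl_effects(panel, cfg)
            g = model_true.genotypic_values(panel)
            rng = np.random.default_rng(seed + 100)
            y = g + rng.normal(0, g.std() * 0.5, len(g))
            ms = markers_from_true_blocks(panel)
            from qtlallele.similarity import genetic_similarity, top_eigenvectors

            basis = top_eigenvectors(genetic_similarity(ms), 10)
            scan = stage1_scan(ms, y, basis)
            fit = stage2_stepwise(ms, scan.preselected, y, basis, h2_cap=0.85)
            # map each true QTL block to its marker id
            strength = [
                (np.ptp(eff), bi)
                for eff, bi in zip(model_true.allele_effects,
                                   model_true.qtl_blocks)
            ]
            top10 = sorted(strength, reverse=True)[:10]
            block_marker = {}
            for m in ms:
                if m.n_snps > 1:
                    for bi, b in enumerate(panel.true_blocks):
                        if b.snp_indices == m.snp_indices:
                            block_marker[bi] = m.id
            for _, bi in top10:
                total += 1
                if block_marker.get(bi) in fit.loci:
                    hits += 1
        assert hits / total >= 0.8


class TestAlleleEffects:
    def test_biallelic_effects_are_symmetric(self, fitted_model):
        model, *_ = fitted_model
        for mid in model.loci:
            values = sorted(set(model.locus_results[mid].allele_effects.values()))
            if len(values) == 2:  # biallelic locus: effects are (e, -e)
                assert sum(values) == pytest.approx(0.0, abs=1e-8)

    def test_sum_to_zero_within_locus(self, fitted_model):
        model, *_ = fitted_model
        for mid in model.loci:
            lr = model.locus_results[mid]
            distinct = sorted(set(lr.allele_effects.values()))
            assert sum(distinct) == pytest.approx(0.0, abs=1e-8)

    def test_balanced_three_allele_closed_form(self):
        # 3 equal groups with hand-set means, no covariates
        codes = np.array([[0] * 10 + [1] * 10 + [2] * 10])
        ms = _marker_set_from_codes(codes, 30)
        means = {0: 1.0, 1: 2.0, 2: 6.0}
        y = _phen([means[c] for c in codes[0]], ms)
        eff = estimate_allele_effects(ms, ["M0"], y, "M0")
        grand = np.mean(list(means.values()))
        for a in (0, 1, 2):
            assert eff[a] == pytest.approx(means[a] - grand, abs=1e-8)

    def test_identical_group_means_give_zero_effects(self):
        codes = np.array([[0] * 10 + [1] * 10])
        ms = _marker_set_from_codes(codes, 20)
        y = _phen([5.0] * 20, ms)
        eff = estimate_allele_effects(ms, ["M0"], y, "M0")
        assert all(abs(e) < 1e-10 for e in eff.values())


class TestContribution:
    def test_single_locus_partial_r2_equals_eta_squared(self):
        rng = np.random.default_rng(9)
        codes = np.array([rng.integers(0, 3, 60)])
        ms = _marker_set_from_codes(codes, 60)
        y_vals = np.array([0.0, 1.0, 2.0])[codes[0]] + rng.normal(0, 0.5, 60)
        y = _phen(y_vals, ms)
        model = stage2_stepwise(ms, ["M0"], y, h2_cap=1.0)
        # one-way ANOVA eta^2 oracle
        grand = y_vals.mean()
        ss_total = ((y_vals - grand) ** 2).sum()
        ss_between = sum(
            (y_vals[codes[0] == a].mean() - grand) ** 2 * (codes[0] == a).sum()
            for a in range(3)
        )
        eta2 = ss_between / ss_total
        assert model.locus_results["M0"].partial_r2 == pytest.approx(
            eta2, abs=1e-8
        )

    def test_orthogonal_loci_partial_r2_sums_to_total(self):
        # balanced 2x2 design -> orthogonal loci
        g1 = np.array([0, 0, 1, 1] * 25)
        g2 = np.array([0, 1, 0, 1] * 25)
        rng = np.random.default_rng(4)
        ms = _marker_set_from_codes(np.stack([g1, g2]), 100)
        y = _phen(1.0 * g1 - 2.0 * g2 + rng.normal(0, 0.3, 100), ms)
        model = stage2_stepwise(ms, ["M0", "M1"], y, h2_cap=1.0)
        df = locus_contribution(model)
        assert df["partial_r2"].sum() == pytest.approx(
            model.total_r2, abs=1e-8
        )

    def test_empty_model_contribution(self):
        codes = np.array([[0, 1] * 10])
        ms = _marker_set_from_codes(codes, 20)
        y = _phen(np.random.default_rng(0).normal(size=20), ms)
        model = stage2_stepwise(ms, [], y, h2_cap=0.8)
        df = locus_contribution(model)
        assert len(df) == 0
        assert df.attrs["total_r2"] == 0.0
        assert df.attrs["unmapped_share"] == pytest.approx(0.8)
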