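"""QC, imputation, |D'| confidence intervals, block detection, markers."""

import numpy as np
import pandas as pd
import pytest

from qtlallele.errors import DataError
from qtlallele.simulate import simulate_founder_genotypes, inject_noise
from qtlallele.snpldb import (
    ALT_HOM,
    GenotypeMatrix,
    HET,
    LDBlock,
    MISSING,
    REF_HOM,
    build_snpldb_markers,
    dprime_ci,
    dprime_ci_from_counts,
    find_ld_blocks,
    impute_missing,
    minor_allele_frequency,
    qc_filter_snps,
)

from conftest import small_config


def _gm(calls, positions=None, chrom="Chr01"):
    calls = np.asarray(calls, dtype=np.int8)
    n_snps = calls.shape[0]
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_snps)]
    snps = pd.DataFrame({
        "chrom": [chrom] * n_snps,
        "pos": positions,
        "ref": ["A"] * n_snps,
        "alt": ["T"] * n_snps,
    })
    acc = [f"s{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(acc, snps, calls)


class TestQC:
    def test_high_missing_het_removed(self):
        n = 20
        row_bad = [MISSING] * 7 + [REF_HOM] * 9 + [ALT_HOM] * 4  # 35% missing
        row_ok = [REF_HOM] * 10 + [ALT_HOM] * 10
        gm = _gm([row_bad, row_ok])
        out, report = qc_filter_snps(gm)
        assert report["n_removed_missing_het"] == 1
        assert out.n_snps == 1

    def test_low_maf_removed(self):
        row_rare = [REF_HOM] * 199 + [ALT_HOM]  # MAF 0.5%
        row_ok = [REF_HOM] * 150 + [ALT_HOM] * 50
        gm = _gm([row_rare, row_ok])
        out, report = qc_filter_snps(gm)
        assert report["n_removed_maf"] == 1
        assert out.n_snps == 1

    def test_het_turned_missing_after_filter(self):
        row = [HET] * 2 + [REF_HOM] * 10 + [ALT_HOM] * 8
        out, _ = qc_filter_snps(_gm([row]))
        assert (out.calls == HET).sum() == 0
        assert (out.calls == MISSING).sum() == 2

    def test_constructed_violation_counts(self):
        rng = np.random.default_rng(2)
        rows, n_rate, n_maf = [], 0, 0
        for i in range(100):
            kind = i % 4
            if kind == 0:  # fails missing rate
                row = [MISSING] * 40 + list(rng.choice([0, 2], 60))
                n_rate += 1
            elif kind == 1:  # fails MAF
                row = [REF_HOM] * 100
                n_maf += 1
            else:
                row = list(rng.choice([0, 2], 100, p=[0.7, 0.3]))
            rows.append(row)
        gm = _gm(rows)
        _, report = qc_filter_snps(gm)
        assert report["n_removed_missing_het"] == n_rate
        assert report["n_removed_maf"] >= n_maf
        assert report["n_input"] == 100


class TestImpute:
    def test_identity_without_missing(self):
        gm = _gm([[REF_HOM, ALT_HOM] * 5])
        out, frac = impute_missing(gm)
        assert frac == 0.0
        assert np.array_equal(out.calls, gm.calls)

    def test_major_allele_fill(self):
        row = [REF_HOM] * 9 + [MISSING]
        out, frac = impute_missing(_gm([row]))
        assert out.calls[0, 9] == REF_HOM
        assert frac == pytest.approx(0.1)

    def test_accuracy_equals_major_allele_baseline(self):
        cfg = small_config(seed=21)
        panel = simulate_founder_genotypes(cfg)
        noisy = inject_noise(panel, missing_rate=0.05, seed=21)
        imputed, _ = impute_missing(noisy)
        mask = noisy.calls == MISSING
        acc = (imputed.calls[mask] == panel.genotypes.calls[mask]).mean()
        # expected accuracy if every missing call is the major allele
        baseline = 0.0
        weight = 0.0
        for i in range(panel.genotypes.n_snps):
            m = mask[i]
            if not m.any():
                continue
            truth = panel.genotypes.calls[i]
            maj = REF_HOM if (noisy.calls[i] == REF_HOM).sum() >= (
                noisy.calls[i] == ALT_HOM).sum() else ALT_HOM
            baseline += (truth[m] == maj).sum()
            weight += m.sum()
        assert acc >= baseline / weight - 1e-9


class TestDprime:
    def test_perfect_ld(self):
        a = np.array([REF_HOM] * 50 + [ALT_HOM] * 50, dtype=np.int8)
        st = dprime_ci(a, a.copy())
        assert st.dprime == pytest.approx(1.0)
        # a clear strong-LD classification: tight CI hugging 1
        assert st.ci_low > 0.90
        assert st.ci_high == pytest.approx(1.0)

    def test_independence(self):
        counts = np.array([[25, 25], [25, 25]])
        st = dprime_ci_from_counts(counts)
        assert st.dprime == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_dprime_and_grid_oracle(self):
        counts = np.array([[40, 10], [10, 40]])
        st = dprime_ci_from_counts(counts)
        # pA = pB = 0.5, p11 = 0.4 -> D = 0.15, Dmax = 0.25, D' = 0.6
        assert st.dprime == pytest.approx(0.6)
        # brute-force fine-grid likelihood oracle
        grid = np.linspace(0, 1, 2001)
        pa = pb = 0.5
        dmax = 0.25
        d = grid * dmax
        p = np.clip(np.stack([
            (1 - pa) * (1 - pb) + d,
            (1 - pa) * pb - d,
            pa * (1 - pb) - d,
            pa * pb + d,
        ], axis=1), 1e-12, None)
        obs = np.array([40, 10, 10, 40])
        ll = (obs * np.log(p)).sum(axis=1)
        lik = np.exp(ll - ll.max())
        cum = np.cumsum(lik) / lik.sum()
        lo = grid[np.searchsorted(cum, 0.05)]
        hi = grid[np.searchsorted(cum, 0.95)]
        assert st.ci_low == pytest.approx(lo, abs=0.01)
        assert st.ci_high == pytest.approx(hi, abs=0.01)

    def test_monomorphic_rejected(self):
        a = np.array([REF_HOM] * 10, dtype=np.int8)
        b = np.array([REF_HOM, ALT_HOM] * 5, dtype=np.int8)
        with pytest.raises(DataError):
            dprime_ci(a, b)


def _three_hap_block(n=200, m=5, seed=4):
    """m SNPs carried on 3 distinct haplotypes, perfect within-block LD."""
    rng = np.random.default_rng(seed)
    haps = np.array([
        [0, 0, 0, 0, 0],
        [1, 1, 0, 1, 0],
        [1, 0, 1, 0, 1],
    ])[:, :m]
    assign = rng.choice(3, n, p=[0.5, 0.3, 0.2])
    calls = np.where(haps[assign].T == 1, ALT_HOM, REF_HOM)
    return calls


class TestBlocks:
    def test_distance_rule_blocks_nothing_beyond_max_dist(self):
        a = np.array([REF_HOM] * 100 + [ALT_HOM] * 100, dtype=np.int8)
        gm = _gm([a, a.copy()], positions=[1, 300_001])
        assert find_ld_blocks(gm) == []

    def test_single_block_of_five_snps(self):
        calls = _three_hap_block()
        gm = _gm(calls, positions=[1, 10_000, 20_000, 30_000, 40_000])
        blocks = find_ld_blocks(gm)
        assert len(blocks) == 1
        assert blocks[0].snp_indices == (0, 1, 2, 3, 4)

    def test_independent_snps_rarely_form_blocks(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            calls = rng.choice([REF_HOM, ALT_HOM], size=(10, 150))
            gm = _gm(calls, positions=[1 + 5000 * i for i in range(10)])
            hits += len(find_ld_blocks(gm)) > 0
        assert hits <= 1  # zero blocks in >= 95% of seeds

    def test_invariance_to_accession_order_and_allele_relabel(self):
        calls = _three_hap_block()
        pos = [1, 10_000, 20_000, 30_000, 40_000]
        gm = _gm(calls, positions=pos)
        base = find_ld_blocks(gm)
        perm = np.random.default_rng(0).permutation(calls.shape[1])
        gm_perm = _gm(calls[:, perm], positions=pos)
        relabeled = calls.copy()
        relabeled[2] = np.where(relabeled[2] == REF_HOM, ALT_HOM, REF_HOM)
        gm_swap = _gm(relabeled, positions=pos)
        for other in (find_ld_blocks(gm_perm), find_ld_blocks(gm_swap)):
            assert [b.snp_indices for b in other] == [b.snp_indices for b in base]

    def test_exact_recovery_of_generated_blocks(self):
        """Noise-free synthetic blocks are recovered exactly at n >= 200.

        Pools are capped at 3 haplotypes: with at most 3 gametic classes
        every within-block pair has |D'| = 1, so true blocks are strong-LD
        throughout and recovery is exact by construction.  Pools of 4+
        haplotypes can legitimately contain all four gametes at some pair
        and then the confidence-interval method is entitled to split the
        block.
        """
        cfg = small_config(
            n_accessions=240, n_chromosomes=2, snps_per_chromosome=30,
            seed=5, drift_concentration=(3.0, 3.0), min_hap_freq=0.05,
            haplotypes_per_block=(2, 3), private_allele_rate=0.0,
        )
        panel = simulate_founder_genotypes(cfg)
        detected = find_ld_blocks(panel.genotypes)
        truth = [b.snp_indices for b in panel.true_blocks]
        assert [b.snp_indices for b in detected] == truth


class TestMarkers:
    def test_three_haplotypes_give_three_alleles(self):
        calls = _three_hap_block()
        gm = _gm(calls, positions=[1, 10_000, 20_000, 30_000, 40_000])
        block = LDBlock("Chr01", (0, 1, 2, 3, 4), 1, 40_000)
        ms = build_snpldb_markers(gm, [block])
        assert len(ms) == 1
        assert ms.markers[0].n_alleles == 3
        assert ms.markers[0].id == "Chr01_BLOCK1"

    def test_rare_haplotype_merges_into_nearest_frequent(self):
        # 0.5% haplotype one SNP away from a 60% haplotype
        n = 200
        haps = {"00000": 119, "11111": 80, "00001": 1}
        columns = []
        for h, cnt in haps.items():
            columns += [h] * cnt
        calls = np.array(
            [[ALT_HOM if c == "1" else REF_HOM for c in h] for h in columns]
        ).T
        gm = _gm(calls, positions=[1, 2, 3, 4, 5])
        ms = build_snpldb_markers(gm, [LDBlock("Chr01", (0, 1, 2, 3, 4), 1, 5)])
        m = ms.markers[0]
        assert sorted(m.alleles) == ["00000", "11111"]
        # the rare carrier ended in the 00000 group
        assert np.bincount(m.codes).tolist() == [120, 80]

    def test_recovered_allele_counts_match_generator(self):
        cfg = small_config(
            n_accessions=300, n_chromosomes=2, snps_per_chromosome=30,
            haplotypes_per_block=(2, 6), seed=6,
            drift_concentration=(5.0, 5.0), min_hap_freq=0.05,
            private_allele_rate=0.0,
        )
        panel = simulate_founder_genotypes(cfg)
        ms = build_snpldb_markers(panel.genotypes, panel.true_blocks)
        block_markers = [m for m in ms if m.n_snps > 1]
        truth = [h.shape[0] for h in panel.block_haplotypes]
        matches = sum(
            m.n_alleles == k for m, k in zip(block_markers, truth)
        )
        assert matches / len(block_markers) >= 0.95

    def test_singletons_become_two_allele_markers(self):
        calls = np.array([[REF_HOM] * 6 + [ALT_HOM] * 6])
        gm = _gm(calls)
        ms = build_snpldb_markers(gm, [])
        assert len(ms) == 1
        assert ms.markers[0].n_alleles == 2
        assert ms.markers[0].id == "Chr01_1000"

    def test_allele_frequencies_sum_to_one(self, true_markers):
        for m in true_markers:
            assert m.allele_freqs().sum() == pytest.approx(1.0)
            assert len(m.codes) == len(true_markers.accessions)

    def test_incomplete_matrix_rejected(self):
        calls = np.array([[REF_HOM] * 5 + [MISSING] * 5])
        with pytest.raises(DataError):
            build_snpldb_markers(_gm(calls), [])
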