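"""Instrument selection, clumping, F filtering, harmonization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from medmr import (
    LDMatrix,
    SimConfig,
    SummaryStatsTable,
    clump,
    f_statistic,
    filter_by_f,
    flipped_export,
    harmonize,
    select_instruments,
    simulate_three_trait_gwas,
)
from medmr.exceptions import DegenerateInstrumentError, ValidationError

from conftest import make_table


def _table_from_rows(rows, trait_id="t"):
    df = pd.DataFrame(rows)
    defaults = {"eaf": 0.3, "n": 10_000, "chrom": "1"}
    for col, val in defaults.items():
        if col not in df:
            df[col] = val
    return SummaryStatsTable(trait_id, "quantitative", df)


class TestSelect:
    def test_strict_threshold(self):
        rows = [
            dict(snp_id="rs1", pos_bp=1, effect_allele="A", other_allele="G",
                 beta=0.1, se=0.02, pval=1e-6),
            dict(snp_id="rs2", pos_bp=2, effect_allele="A", other_allele="G",
                 beta=0.1, se=0.02, pval=2e-5),
            dict(snp_id="rs3", pos_bp=3, effect_allele="A", other_allele="G",
                 beta=0.1, se=0.02, pval=0.3),
        ]
        assert select_instruments(_table_from_rows(rows), 1e-5) == ["rs1"]

    def test_near_one_threshold_selects_all(self, small_table):
        ids = select_instruments(small_table, 1 - 1e-12)
        assert set(ids) == set(small_table.snp_ids)

    def test_matches_bruteforce_on_random_table(self):
        table = make_table(n=1000, seed=7)
        ids = select_instruments(table, 5e-8)
        brute = sorted(
            table.df.loc[table.df["pval"] < 5e-8, "snp_id"],
            key=lambda s: (float(table.df.set_index("snp_id").loc[s, "pval"]), s),
        )
        assert ids == brute

    def test_bad_threshold(self, small_table):
        with pytest.raises(ValidationError):
            select_instruments(small_table, 0.0)


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,expected", [(0.1, 0.02, 25.0), (0.03, 0.01, 9.0), (0.0, 0.5, 0.0)]
    )
    def test_values(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    def test_se_must_be_positive(self):
        with pytest.raises(ValidationError):
            f_statistic(0.1, 0.0)

    def test_filter_keeps_strictly_above_ten(self):
        rows = [
            dict(snp_id="rs1", pos_bp=1, effect_allele="A", other_allele="G",
                 beta=0.1, se=0.02, pval=1e-6),  # F = 25
            dict(snp_id="rs2", pos_bp=2, effect_allele="A", other_allele="G",
                 beta=0.03, se=0.01, pval=1e-6),  # F = 9
        ]
        table = _table_from_rows(rows)
        assert filter_by_f(table, ["rs1", "rs2"], 10.0) == ["rs1"]


class TestClump:
    def _pair_table(self, pos2, pval2=1e-6):
        rows = [
            dict(snp_id="rs1", pos_bp=1_000_000, effect_allele="A",
                 other_allele="G", beta=0.1, se=0.01, pval=1e-8),
            dict(snp_id="rs2", pos_bp=pos2, effect_allele="A",
                 other_allele="G", beta=0.1, se=0.02, pval=pval2),
        ]
        return _table_from_rows(rows)

    def test_correlated_neighbor_removed(self):
        table = self._pair_table(1_001_000)  # 1 kb away
        r = np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]])
        ld = LDMatrix(["rs1", "rs2"], r)
        assert clump(table, ["rs1", "rs2"], ld) == ["rs1"]

    def test_distant_snp_survives_despite_ld(self):
        table = self._pair_table(1_000_000 + 20_000 * 1_000)  # 20,000 kb away
        r = np.array([[1.0, np.sqrt(0.9)], [np.sqrt(0.9), 1.0]])
        ld = LDMatrix(["rs1", "rs2"], r)
        assert set(clump(table, ["rs1", "rs2"], ld)) == {"rs1", "rs2"}

    def test_missing_candidate_raises(self):
        table = self._pair_table(1_001_000)
        ld = LDMatrix(["rs1"], np.eye(1))
        with pytest.raises(ValidationError, match="rs2"):
            clump(table, ["rs1", "rs2"], ld)

    def test_against_bruteforce_oracle(self):
        cfg = SimConfig(
            seed=13, n_snps=50, n_instruments=5, n_mediator_instruments=0,
            ld_block_size=10, ld_rho=0.9, sigma_gamma=0.15,
        )
        x, *_, ld, _ = simulate_three_trait_gwas(cfg)
        candidates = x.snp_ids
        kept = clump(x, candidates, ld, r2_threshold=0.01, window_kb=10_000)

        # independent greedy reference re-checking every pair from scratch
        info = x.df.set_index("snp_id")
        remaining = sorted(candidates, key=lambda s: (info.loc[s, "pval"], s))
        expected = []
        while remaining:
            index = remaining[0]
            expected.append(index)
            remaining = [
                s
                for s in remaining[1:]
                if not (
                    info.loc[s, "chrom"] == info.loc[index, "chrom"]
                    and abs(info.loc[s, "pos_bp"] - info.loc[index, "pos_bp"]) <= 1e7
                    and ld.r2(s, index) >= 0.01
                )
            ]
        assert kept == expected
        # every surviving pair is clump-independent
        for a, b in itertools.combinations(kept, 2):
            close = (
                info.loc[a, "chrom"] == info.loc[b, "chrom"]
                and abs(info.loc[a, "pos_bp"] - info.loc[b, "pos_bp"]) <= 1e7
            )
            assert not (close and ld.r2(a, b) >= 0.01)

    def test_order_independence(self):
        cfg = SimConfig(
            seed=17, n_snps=40, n_instruments=5, n_mediator_instruments=0,
            ld_block_size=8, ld_rho=0.8,
        )
        x, *_, ld, _ = simulate_three_trait_gwas(cfg)
        ids = x.snp_ids
        ref = clump(x, ids, ld)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(rng.permutation(ids))
            assert clump(x, perm, ld) == ref


class TestHarmonize:
    def _pair(self, e_alleles, o_alleles, e_eaf=0.3, o_eaf=0.3, o_beta=0.1):
        exp = _table_from_rows([
            dict(snp_id="rs1", pos_bp=1, effect_allele=e_alleles[0],
                 other_allele=e_alleles[1], eaf=e_eaf, beta=0.2, se=0.02, pval=1e-8),
        ], "exp")
        out = _table_from_rows([
            dict(snp_id="rs1", pos_bp=1, effect_allele=o_alleles[0],
                 other_allele=o_alleles[1], eaf=o_eaf, beta=o_beta, se=0.03, pval=0.01),
        ], "out")
        return exp, out

    def test_swapped_alleles_negate_outcome(self):
        exp, out = self._pair(("A", "G"), ("G", "A"))
        hs = harmonize(exp, out, ["rs1"])
        assert hs.df["Gamma_hat"].iloc[0] == pytest.approx(-0.1)

    def test_strand_complement_kept_as_is(self):
        exp, out = self._pair(("A", "G"), ("T", "C"))
        hs = harmonize(exp, out, ["rs1"])
        assert hs.df["Gamma_hat"].iloc[0] == pytest.approx(0.1)

    def test_strand_complement_swapped_negates(self):
        exp, out = self._pair(("A", "G"), ("C", "T"))
        hs = harmonize(exp, out, ["rs1"])
        assert hs.df["Gamma_hat"].iloc[0] == pytest.approx(-0.1)

    def test_palindromic_ambiguous_eaf_dropped(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), e_eaf=0.51, o_eaf=0.49)
        with pytest.raises(ValidationError):  # single SNP -> empty set
            harmonize(exp, out, ["rs1"])

    def test_palindromic_opposite_strand_flipped(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), e_eaf=0.2, o_eaf=0.8)
        hs = harmonize(exp, out, ["rs1"])
        assert hs.df["Gamma_hat"].iloc[0] == pytest.approx(-0.1)

    def test_palindromic_same_strand_kept(self):
        exp, out = self._pair(("G", "C"), ("G", "C"), e_eaf=0.2, o_eaf=0.25)
        hs = harmonize(exp, out, ["rs1"])
        assert hs.df["Gamma_hat"].iloc[0] == pytest.approx(0.1)

    def test_irreconcilable_pair_dropped_with_reason(self):
        exp, out = self._pair(("A", "C"), ("A", "G"))
        with pytest.raises(ValidationError):
            harmonize(exp, out, ["rs1"])

    def test_flipped_export_roundtrip(self, sim_bundle):
        x, _, y, _, truth = sim_bundle
        hs = harmonize(x, y, truth.instrument_ids)
        hs_flipped = harmonize(x, flipped_export(y), truth.instrument_ids)
        pd.testing.assert_frame_equal(hs.df, hs_flipped.df)

    def test_idempotent_on_aligned_tables(self, sim_bundle):
        # simulator tables share alleles: harmonization must not alter effects
        x, _, y, _, truth = sim_bundle
        hs = harmonize(x, y, truth.instrument_ids)
        ydf = y.df.set_index("snp_id")
        for _, row in hs.df.iterrows():
            assert row["Gamma_hat"] == ydf.loc[row["snp_id"], "beta"]


def test_qc_chain_selects_mostly_true_instruments():
    """At large n, select->clump->F recovers essentially only true instruments."""
    hits, true_hits = 0, 0
    for seed in range(10):
        cfg = SimConfig(
            seed=seed, n_x=10**6, n_snps=100, n_instruments=20,
            n_mediator_instruments=0, palindromic_frac=0.0,
        )
        x, *_, ld, truth = simulate_three_trait_gwas(cfg)
        ids = select_instruments(x, 1e-5)
        ids = clump(x, ids, ld)
        ids = filter_by_f(x, ids, 10)
        hits += len(ids)
        true_hits += len(set(ids) & set(truth.instrument_ids))
    assert true_hits / hits >= 0.95
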