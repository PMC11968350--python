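"""Instrument selection and QC: thresholds, clumping, F, Steiger."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mrscreen import instruments
from mrscreen.instruments import (
    LDMatrix,
    clump,
    exclude_outcome_associated,
    f_statistic,
    filter_weak,
    r_squared_per_variant,
    select_by_pvalue,
    steiger_filter,
)
from mrscreen.gwas_io import AssociationRecord
from mrscreen.synthetic_data import simulate_pair

from conftest import make_pair, make_table


class TestSelectByPvalue:
    def test_filter_count(self, rng):
        pvals = np.concatenate([rng.uniform(1e-10, 4e-8, 7), rng.uniform(1e-6, 1, 93)])
        rows = [(f"rs{i}", "A", "G", 0.3, 0.1, 0.02, p, 1000) for i, p in enumerate(pvals)]
        t = make_table(rows=rows)
        assert len(select_by_pvalue(t, 5e-8)) == 7

    @pytest.mark.parametrize("trait_class,expected", [
        ("gut_microbiota", 1e-5),
        ("metabolite", 1e-5),
        ("skin_microbiota", 5e-5),
        ("immune_cell", 5e-8),
        ("disease", 5e-8),
    ])
    def test_auto_threshold_by_class(self, trait_class, expected):
        assert instruments.resolve_threshold(trait_class) == expected
        rows = [("rs1", "A", "G", 0.3, 0.1, 0.02, expected * 0.99, 1000),
                ("rs2", "T", "C", 0.3, 0.1, 0.02, expected * 1.01, 1000)]
        t = make_table(trait_class=trait_class, rows=rows)
        kept = select_by_pvalue(t, "auto")
        assert [str(s) for s in kept.df["SNP"]] == ["rs1"]


def _ld(ids, r2):
    return LDMatrix(variant_ids=ids, r2=np.asarray(r2, float))


class TestClump:
    def test_independent_variants_all_kept(self):
        t = make_table(rows=[(f"rs{i}", "A", "G", 0.3, 0.1, 0.02, 1e-8, 1000)
                             for i in (1, 2, 3)])
        ld = _ld(["rs1", "rs2", "rs3"], np.eye(3))
        assert len(clump(t, ld, 0.001)) == 3

    def test_greedy_keeps_smaller_p(self):
        t = make_table(rows=[("rs1", "A", "G", 0.3, 0.1, 0.02, 1e-10, 1000),
                             ("rs2", "T", "C", 0.3, 0.1, 0.02, 1e-8, 1000)])
        ld = _ld(["rs1", "rs2"], [[1, 0.5], [0.5, 1]])
        kept = clump(t, ld, 0.001)
        assert [str(s) for s in kept.df["SNP"]] == ["rs1"]

    def test_chain_case_matches_enumeration_oracle(self):
        # r2(1,2)=r2(2,3)=0.002 block greedy; r2(1,3)=0.0005 is compatible
        ids = ["rs1", "rs2", "rs3"]
        r2 = [[1, 0.002, 0.0005], [0.002, 1, 0.002], [0.0005, 0.002, 1]]
        pv = [1e-10, 1e-9, 1e-8]
        t = make_table(rows=[(v, "A", "G", 0.3, 0.1, 0.02, p, 1000)
                             for v, p in zip(ids, pv)])
        kept = clump(t, _ld(ids, r2), 0.001)
        assert sorted(str(s) for s in kept.df["SNP"]) == ["rs1", "rs3"]
        # oracle: greedy over p order by exhaustive prefix check
        r2a = np.asarray(r2)
        order = np.argsort(pv)
        oracle = []
        for i in order:
            if all(r2a[i, k] < 0.001 for k in oracle):
                oracle.append(i)
        assert sorted(ids[i] for i in oracle) == ["rs1", "rs3"]

    def test_greedy_maximality_property(self, rng):
        # no dropped variant is compatible with all kept variants preceding it
        for _ in range(20):
            m = 8
            a = rng.uniform(0, 0.004, (m, m))
            r2 = np.clip((a + a.T) / 2, 0, 1)
            np.fill_diagonal(r2, 1.0)
            ids = [f"rs{i}" for i in range(m)]
            pv = rng.uniform(1e-12, 1e-6, m)
            t = make_table(rows=[(v, "A", "G", 0.3, 0.1, 0.02, p, 1000)
                                 for v, p in zip(ids, pv)])
            kept = [str(s) for s in clump(t, _ld(ids, r2), 0.001).df["SNP"]]
            kept_idx = [ids.index(v) for v in kept]
            order = sorted(range(m), key=lambda i: (pv[i], ids[i]))
            for i in order:
                if ids[i] in kept:
                    continue
                preceding = [k for k in kept_idx if order.index(k) < order.index(i)]
                assert any(r2[i, k] >= 0.001 for k in preceding)

    def test_missing_candidate_errors(self):
        t = make_table(rows=[("rs1", "A", "G", 0.3, 0.1, 0.02, 1e-8, 1000)])
        with pytest.raises(KeyError, match="rs1"):
            clump(t, _ld(["rsX"], np.eye(1)), 0.001)


class TestRSquared:
    def test_from_beta_eaf_direct(self):
        rec = AssociationRecord("rs1", "A", "G", beta=0.1, se=0.02, pval=1e-6, eaf=0.5, n=1000)
        assert r_squared_per_variant(rec, "from_beta_eaf") == pytest.approx(0.005)

    def test_from_pn_matches_frozen_t_quantile(self):
        # two-sided 0.05 at df 998: t = 1.962343846216334 (independent qt oracle)
        rec = AssociationRecord("rs1", "A", "G", beta=0.05, se=0.0255, pval=0.05, n=1000)
        t = 1.962343846216334
        expected = t * t / (t * t + 998)
        assert r_squared_per_variant(rec, "from_pn") == pytest.approx(expected, rel=1e-9)

    def test_zero_beta_gives_zero(self):
        rec = AssociationRecord("rs1", "A", "G", beta=0.0, se=0.02, pval=1.0, eaf=0.3, n=1000)
        assert r_squared_per_variant(rec, "from_pn") == 0.0
        assert r_squared_per_variant(rec, "from_beta_eaf") == 0.0

    def test_missing_inputs_error(self):
        rec = AssociationRecord("rs1", "A", "G", beta=0.1, se=0.02, pval=1e-6)
        with pytest.raises(ValueError, match="requires n"):
            r_squared_per_variant(rec, "from_pn")
        with pytest.raises(ValueError, match="requires eaf"):
            r_squared_per_variant(rec, "from_beta_eaf")


class TestFStatistic:
    def test_printed_formula_hand_values(self):
        assert f_statistic(0.01, 1000, 10) == pytest.approx((0.01 * 989) / (10 * 0.99))
        assert f_statistic(0.01, 1000, 10) == pytest.approx(0.99899, abs=1e-5)
        assert f_statistic(0.038, 10_000, 1) == pytest.approx((0.038 * 9998) / 0.962)
        assert f_statistic(0.038, 10_000, 1) == pytest.approx(394.94, abs=0.01)
        assert f_statistic(0.0, 500, 3) == 0.0

    def test_monotonicity(self):
        f = [f_statistic(r2, 5000, 5) for r2 in (0.001, 0.01, 0.05, 0.2)]
        assert all(a < b for a, b in zip(f, f[1:]))
        f = [f_statistic(0.05, 5000, k) for k in (1, 2, 5, 10)]
        assert all(a > b for a, b in zip(f, f[1:]))

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 1000, 1)
        with pytest.raises(ValueError):
            f_statistic(0.1, 5, 10)


class TestOutcomeExclusion:
    def test_threshold_rule(self):
        pair = make_pair([0.1, 0.1, 0.1], [0.02] * 3,
                         [0.05, 0.02, 0.0], [0.02] * 3)
        # z = 2.5 (p~0.0124) dropped; z = 1.0 (p~0.317) kept; z = 0 kept
        out = exclude_outcome_associated(pair, 0.05)
        assert out.variant_ids == ["rs2", "rs3"]
        assert out.drop_log[0].reason == "outcome_associated"

    def test_zero_cut_drops_nothing(self):
        pair = make_pair([0.1, 0.1], [0.02] * 2, [0.5, 0.9], [0.02] * 2)
        assert exclude_outcome_associated(pair, 0.0).j == 2


class TestSteigerFilter:
    def test_forward_kept_reverse_dropped(self):
        # rs1: strong on exposure, null on outcome; rs2: the reverse
        pair = make_pair([0.10, 0.002], [0.02, 0.02], [0.002, 0.10], [0.02, 0.02],
                         n_exp=10_000, n_out=10_000)
        out = steiger_filter(pair)
        assert out.variant_ids == ["rs1"]
        assert out.drop_log[0].reason == "steiger_reverse"

    def test_tie_kept_and_flagged(self):
        pair = make_pair([0.1], [0.02], [0.1], [0.02], n_exp=10_000, n_out=10_000)
        out = steiger_filter(pair)
        assert out.j == 1
        assert out.flags.get("steiger_tie") == ["rs1"]


class TestWeakFilter:
    def test_strong_instruments_survive_weak_removed(self):
        strong = simulate_pair(30, 0.2, n_exposure=50_000, per_variant_r2=0.003, seed=101)
        assert filter_weak(strong).j == 30
        weak = simulate_pair(30, 0.2, n_exposure=300, n_outcome=300,
                             per_variant_r2=0.003, seed=101)
        # true per-variant F ~ 0.9; an occasional sampling fluke may pass
        assert filter_weak(weak).j <= 3

    def test_filter_composition_matches_pipeline_order(self):
        from mrscreen.pipeline import ScreenSettings, screen_one
        from mrscreen.synthetic_data import SimConfig, simulate_triplet
        from mrscreen.gwas_io import harmonize

        sim = simulate_triplet(SimConfig(seed=21, m_snps=100, j_causal=10))
        st = ScreenSettings(nb_sim=200)
        row = screen_one(sim.exposure, sim.outcome, sim.ld, st, seed=5)
        cand = select_by_pvalue(sim.exposure, "auto")
        cand = clump(cand, sim.ld, st.clump_r2)
        pair = harmonize(cand, sim.outcome, st.palindrome_window)
        pair = exclude_outcome_associated(pair, st.outcome_p_cut)
        pair = filter_weak(pair, st.f_cutoff)
        pair = steiger_filter(pair)
        assert row["status"] in ("ok", "pleiotropy_unresolved")
        if row["status"] == "ok":
            assert row["nsnp"] == pair.j


def test_ld_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        LDMatrix(["a", "b"], np.array([[1, 0.5], [0.2, 1]]))
    with pytest.raises(ValueError, match="diagonal"):
        LDMatrix(["a", "b"], np.array([[1, 0.1], [0.1, 0.9]]))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        LDMatrix(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]))


def test_ld_matrix_tsv_round_trip(tmp_path, rng):
    from mrscreen.instruments import read_ld_matrix, write_ld_matrix

    a = rng.uniform(0, 0.1, (4, 4))
    r2 = (a + a.T) / 2
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix([f"rs{i}" for i in range(4)], r2)
    p = tmp_path / "ld.tsv"
    write_ld_matrix(ld, p)
    back = read_ld_matrix(p)
    assert back.variant_ids == ld.variant_ids
    np.testing.assert_allclose(back.r2, ld.r2)
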