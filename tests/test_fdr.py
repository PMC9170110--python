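"""Genomic inflation control, conditional Q-Q curves and cond/conjFDR against
brute-force counting oracles."""

import numpy as np
import pandas as pd
import pytest

from pleiomix import (
    CondFdrAnalysis,
    FdrConfig,
    GenerativeParams,
    build_ld_reference,
    conditional_qq,
    conjfdr,
    inflation_correct,
    simulate_pair,
)
from pleiomix.fdr import condfdr_grid
from pleiomix.sumstats import PairedSumstats

RAW = FdrConfig(n_prune=1, prune_r2=None, min_count=1, monotone_p1=False)


def pair_from_p(p1, p2, ld=None):
    """PairedSumstats with prescribed p-values (z backfilled)."""
    from scipy.stats import norm

    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n = p1.size
    t = pd.DataFrame(
        {
            "SNP": [f"snp{i + 1:07d}" for i in range(n)],
            "CHR": 1,
            "BP": 1_000_000 + 10_000 * np.arange(n),
            "A1": "A",
            "A2": "G",
            "Z_A": norm.isf(p1 / 2),
            "Z_B": norm.isf(p2 / 2),
            "P_A": p1,
            "P_B": p2,
            "N_A": 10_000,
            "N_B": 10_000,
        }
    )
    return PairedSumstats(t)


class TestInflation:
    def test_null_lambda_near_one(self):
        ld = build_ld_reference(1000, 20, 0.0)
        p = GenerativeParams(M=20_000, pi1=0, pi2=0, pi12=0, seed=1)
        pair, _ = simulate_pair(p, ld)
        _, lam_a, lam_b = inflation_correct(pair, ld, FdrConfig(apply_lambda_floor=False))
        assert 0.95 <= lam_a <= 1.05 and 0.95 <= lam_b <= 1.05

    def test_doubled_z_gives_lambda_four(self):
        ld = build_ld_reference(1000, 20, 0.0)
        p = GenerativeParams(M=20_000, pi1=0, pi2=0, pi12=0, seed=2)
        pair, _ = simulate_pair(p, ld)
        doubled = PairedSumstats(pair.table.assign(Z_A=2 * pair.table["Z_A"]))
        corr, lam_a, _ = inflation_correct(doubled, ld, FdrConfig(apply_lambda_floor=False))
        assert lam_a == pytest.approx(4.0, rel=0.06)
        np.testing.assert_allclose(
            corr.table["Z_A"], pair.table["Z_A"] * 2 / np.sqrt(lam_a), rtol=1e-12
        )

    def test_lambda_floor_prevents_deflation(self):
        ld = build_ld_reference(100, 10, 0.0)
        p = GenerativeParams(M=1000, pi1=0, pi2=0, pi12=0, seed=3)
        pair, _ = simulate_pair(p, ld)
        shrunk = PairedSumstats(pair.table.assign(Z_A=0.5 * pair.table["Z_A"]))
        corr, lam_a, _ = inflation_correct(shrunk, ld)
        assert lam_a == 1.0
        np.testing.assert_allclose(corr.table["Z_A"], shrunk.table["Z_A"])


class TestConditionalQQ:
    def test_hand_computed_ranks(self):
        ld = build_ld_reference(1, 3, 0.0)
        pair = pair_from_p([0.02, 0.2, 0.9], [0.05, 0.05, 0.05], ld)
        qq = conditional_qq(pair, ld, thresholds=[0.1], config=RAW)
        (thr, n, nominal, empirical) = qq.strata[0]
        assert n == 3
        i = np.argmax(nominal)  # the p1 = 0.02 point
        assert nominal[i] == pytest.approx(-np.log10(0.02))  # 1.699
        assert empirical[i] == pytest.approx(-np.log10(1 / 4))  # 0.602

    def test_whole_sample_stratum_equals_unconditional(self):
        ld = build_ld_reference(2, 5, 0.0)
        rng = np.random.default_rng(0)
        p1, p2 = rng.uniform(size=10), rng.uniform(size=10)
        pair = pair_from_p(p1, p2, ld)
        qq = conditional_qq(pair, ld, thresholds=[1.0], config=RAW)
        thr, n, nominal, empirical = qq.strata[0]
        order = np.argsort(p1)
        ranks = np.empty(10)
        # empirical quantile of each sorted p1 is rank/(n+1)
        expect = {-np.log10(p): -np.log10((i + 1) / 11)
                  for i, p in enumerate(np.sort(p1))}
        for x, y in zip(nominal, empirical):
            assert y == pytest.approx(expect[x])

    def test_invariants_and_empty_stratum(self):
        ld = build_ld_reference(10, 10, 0.0)
        rng = np.random.default_rng(1)
        pair = pair_from_p(rng.uniform(size=100), rng.uniform(0.01, 1.0, size=100), ld)
        with pytest.warns(UserWarning, match="empty"):
            qq = conditional_qq(pair, ld, thresholds=[1.0, 0.1, 0.001], config=RAW)
        # the p2<=0.001 stratum is empty and omitted
        assert [s[0] for s in qq.strata] == [1.0, 0.1]
        counts = [s[1] for s in qq.strata]
        assert counts[0] >= counts[1]
        for _, _, nominal, empirical in qq.strata:
            assert (np.diff(empirical[np.argsort(nominal)]) >= -1e-12).all()


class TestCondFdr:
    def test_toy_stratum_exact_node(self):
        # 4 variants, p1 = {0.001, 0.01, 0.05, 0.5}, all with p2 <= 0.1:
        # condFDR at the p1=0.01 variant = 0.01 / (2/4) = 0.02
        ld = build_ld_reference(1, 4, 0.0)
        pair = pair_from_p([0.001, 0.01, 0.05, 0.5], [0.1, 0.1, 0.1, 0.1], ld)
        res = CondFdrAnalysis(pair, ld, RAW).fit(correct_inflation=False)
        i = int(np.flatnonzero(pair.table["P_A"] == 0.01)[0])
        assert res.table.loc[i, "CONDFDR_AB"] == pytest.approx(0.02, abs=1e-12)

    def test_degenerate_stratum_is_unconditional_fdr(self):
        # conditioning at p2 <= 1 reduces the lattice to the unconditional
        # empirical FDR p1 / ecdf(p1) at every node
        rng = np.random.default_rng(2)
        p1 = rng.uniform(size=10)
        p2 = np.ones(10)
        cf, F = condfdr_grid(p1, p2, [np.ones(10, dtype=bool)], RAW)
        for k1, x1 in enumerate(RAW.x1_grid):
            ecdf = (p1 <= 10 ** -x1 + 1e-15).mean()
            expect = min(10 ** -x1 / ecdf, 1.0) if ecdf else 1.0
            assert cf[k1, 0] == pytest.approx(expect, abs=1e-12)

    def test_condfdr_at_least_p(self):
        ld = build_ld_reference(20, 10, 0.0)
        rng = np.random.default_rng(3)
        pair = pair_from_p(rng.uniform(size=200) ** 3, rng.uniform(size=200) ** 2, ld)
        for cfg in (RAW, FdrConfig(n_prune=1, prune_r2=None, min_count=1)):
            res = CondFdrAnalysis(pair, ld, cfg).fit(correct_inflation=False)
            t = res.table
            assert (t["CONDFDR_AB"] >= t["P_A"] - 1e-12).all()
            assert (t["CONDFDR_BA"] >= t["P_B"] - 1e-12).all()
            assert (t["CONJFDR"] >= t[["CONDFDR_AB", "CONDFDR_BA"]].max(axis=1) - 1e-15).all()

    def test_grid_nodes_match_brute_force_counting(self):
        # 10-variant toy: every lattice node with a populated conditioning
        # stratum must equal the double-loop counting estimate exactly
        ld = build_ld_reference(2, 5, 0.0)
        rng = np.random.default_rng(4)
        p1 = np.round(rng.uniform(size=10) ** 2, 4) + 1e-4
        p2 = np.round(rng.uniform(size=10), 4) + 1e-4
        pair = pair_from_p(p1, p2, ld)
        cf, F = condfdr_grid(p1, p2, [np.ones(10, dtype=bool)], RAW)
        for k1, x1 in enumerate(RAW.x1_grid[:40]):
            for k2, x2 in enumerate(RAW.x2_grid[:30]):
                denom = (p2 <= 10 ** -x2 + 1e-15).sum()
                if denom == 0:
                    continue
                num = ((p1 <= 10 ** -x1 + 1e-15) & (p2 <= 10 ** -x2 + 1e-15)).sum()
                expect = min(10 ** -x1 / (num / denom), 1.0) if num else 1.0
                assert cf[k1, k2] == pytest.approx(expect, abs=1e-12), (x1, x2)

    def test_monotone_envelope_dominates_raw(self):
        ld = build_ld_reference(4, 5, 0.0)
        rng = np.random.default_rng(5)
        p1, p2 = rng.uniform(size=20) ** 2, rng.uniform(size=20)
        cfg_mono = FdrConfig(n_prune=1, prune_r2=None, min_count=1, monotone_p1=True)
        cf_raw, _ = condfdr_grid(p1, p2, [np.ones(20, dtype=bool)], RAW)
        cf_mono, _ = condfdr_grid(p1, p2, [np.ones(20, dtype=bool)], cfg_mono)
        assert (cf_mono >= cf_raw - 1e-15).all()
        # nonincreasing along the -log10 p1 axis == nondecreasing in p1
        assert (np.diff(cf_mono, axis=0) <= 1e-15).all()

    def test_small_stratum_inherits_coarser_column(self):
        p1 = np.linspace(0.01, 0.9, 40)
        p2 = np.concatenate([np.full(39, 0.9), [1e-4]])
        cfg = FdrConfig(n_prune=1, prune_r2=None, min_count=5, monotone_p1=False)
        cf, F = condfdr_grid(p1, p2, [np.ones(40, dtype=bool)], cfg)
        # the p2 <= 1e-3 column holds a single variant (< min_count) and must
        # equal the nearest valid coarser column (p2 <= ~0.9 stratum)
        k_strict = np.searchsorted(cfg.x2_grid, 3.0)
        k_valid = np.searchsorted(cfg.x2_grid, 0.04)
        np.testing.assert_allclose(F[:, k_strict], F[:, k_valid])


class TestConjFdr:
    def test_elementwise_max_and_errors(self):
        assert conjfdr([0.004], [0.02])[0] == pytest.approx(0.02)
        np.testing.assert_allclose(conjfdr([0.3, 0.3], [0.3, 0.3]), [0.3, 0.3])
        got = conjfdr([0.1, 0.5, 0.01, 1.0, 0.2, 0.6], [0.2, 0.4, 0.3, 0.9, 0.2, 0.05])
        want = [max(a, b) for a, b in zip([0.1, 0.5, 0.01, 1.0, 0.2, 0.6],
                                          [0.2, 0.4, 0.3, 0.9, 0.2, 0.05])]
        np.testing.assert_allclose(got, want)
        with pytest.raises(ValueError, match="length"):
            conjfdr([0.1], [0.1, 0.2])

    def test_select_significant_strict_boundaries(self):
        ld = build_ld_reference(2, 5, 0.0)
        pair = pair_from_p(np.linspace(0.01, 0.9, 10), np.linspace(0.01, 0.9, 10), ld)
        res = CondFdrAnalysis(pair, ld, RAW).fit(correct_inflation=False)
        res.table["CONJFDR"] = [0.05, 0.049, 1.0, 0.01, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        res.table["CONDFDR_AB"] = 1.0
        res.table["CONDFDR_BA"] = 1.0
        sel = res.select_significant()
        assert sel["conj"].sum() == 2  # 0.05 itself excluded (strict <)
        assert sel["cond_ab"].sum() == 0

    def test_swapping_traits_swaps_directions(self):
        ld = build_ld_reference(4, 5, 0.0)
        rng = np.random.default_rng(6)
        pair = pair_from_p(rng.uniform(size=20) ** 2, rng.uniform(size=20) ** 2, ld)
        res = CondFdrAnalysis(pair, ld, RAW).fit(correct_inflation=False)
        res_sw = CondFdrAnalysis(pair.swapped(), ld, RAW).fit(correct_inflation=False)
        np.testing.assert_allclose(res_sw.table["CONDFDR_AB"], res.table["CONDFDR_BA"])
        np.testing.assert_allclose(res_sw.table["CONDFDR_BA"], res.table["CONDFDR_AB"])
        np.testing.assert_allclose(res_sw.table["CONJFDR"], res.table["CONJFDR"])

    def test_output_tables(self, tmp_path):
        ld = build_ld_reference(2, 5, 0.0)
        pair = pair_from_p(np.linspace(0.01, 0.9, 10), np.linspace(0.05, 0.9, 10), ld)
        res = CondFdrAnalysis(pair, ld, RAW).fit()
        res.to_tsv(tmp_path / "fdr.tsv")
        back = pd.read_csv(tmp_path / "fdr.tsv", sep="\t")
        assert list(back.columns) == ["SNP", "CHR", "BP", "Z_A", "Z_B",
                                      "P_A", "P_B", "CONDFDR_AB", "CONDFDR_BA", "CONJFDR"]
        res.grid_to_tsv(tmp_path / "grid.tsv")
        grid = pd.read_csv(tmp_path / "grid.tsv", sep="\t", index_col=0)
        assert grid.shape == (len(RAW.x1_grid), len(RAW.x2_grid))
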