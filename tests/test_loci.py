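"""Clumping, lead selection, locus merging, effect direction and novelty."""

import numpy as np
import pandas as pd
import pytest

from pleiomix import (
    GenomicInterval,
    KnownLociCatalog,
    assign_effect_direction,
    build_ld_reference,
    clump_independent_significant,
    define_loci,
    harmonize_pair,
    locus_table,
    novelty_check,
    select_lead_snps,
)
from pleiomix.ld import LDReference
from pleiomix.loci import Locus

from _oracles import define_loci_oracle, greedy_clump_oracle, random_locus_toy
from conftest import make_sumstats


def custom_ld(snps, chroms, bps, blocks, block_index):
    template = pd.DataFrame({"SNP": snps, "CHR": chroms, "BP": bps})
    return LDReference(template, blocks, np.asarray(block_index, dtype=np.int64))


def corr_block(n, r):
    m = np.full((n, n), r, dtype=float)
    np.fill_diagonal(m, 1.0)
    return m


def sig_frame(snps, chroms, bps, fdr, p=None):
    return pd.DataFrame({
        "SNP": snps, "CHR": chroms, "BP": bps, "FDR": fdr,
        "P": p if p is not None else fdr,
    })


class TestClumping:
    def test_linked_pair_keeps_best_fdr(self):
        # r = sqrt(0.7) -> r^2 = 0.7 >= 0.6
        ld = custom_ld(["a", "b"], [1, 1], [100, 200],
                       [corr_block(2, np.sqrt(0.7))], [0, 0])
        sig = sig_frame(["a", "b"], [1, 1], [100, 200], [0.001, 0.01])
        assert clump_independent_significant(sig, ld) == ["a"]

    def test_no_ld_keeps_all(self, ld_no_ld):
        t = ld_no_ld.template.iloc[:6]
        sig = sig_frame(t["SNP"], t["CHR"], t["BP"], np.linspace(0.001, 0.006, 6))
        assert len(clump_independent_significant(sig, ld_no_ld)) == 6

    def test_eight_variant_toy_matches_oracle(self):
        rng = np.random.default_rng(13)
        load = rng.normal(size=(8, 2))
        cov = load @ load.T + np.diag(rng.uniform(0.1, 1, 8))
        d = np.sqrt(np.diag(cov))
        block = cov / np.outer(d, d)
        snps = list("abcdefgh")
        bps = np.arange(8) * 1000 + 100
        ld = custom_ld(snps, [1] * 8, bps, [block], [0] * 8)
        fdr = rng.uniform(0, 0.01, 8)
        p = fdr / 2
        sig = sig_frame(snps, [1] * 8, bps, fdr, p)
        rows = sig.to_dict("records")
        lut = lambda s1, s2: ld.r2(ld.row_of(s1), ld.row_of(s2))
        for thr in (0.1, 0.3, 0.6):
            got = clump_independent_significant(sig, ld, thr)
            assert got == greedy_clump_oracle(rows, lut, thr)

    def test_variant_missing_from_ld_is_independent(self, ld_no_ld):
        sig = sig_frame(["nope1", "nope2"], [1, 1], [5, 6], [0.001, 0.002])
        with pytest.warns(UserWarning, match="absent"):
            assert clump_independent_significant(sig, ld_no_ld) == ["nope1", "nope2"]


class TestLeadSelection:
    def test_r2_03_pair_gives_one_lead(self):
        ld = custom_ld(["a", "b"], [1, 1], [100, 200],
                       [corr_block(2, np.sqrt(0.3))], [0, 0])
        sig = sig_frame(["a", "b"], [1, 1], [100, 200], [0.001, 0.01])
        ind = clump_independent_significant(sig, ld)  # r^2=0.3 < 0.6: both kept
        assert ind == ["a", "b"]
        assert select_lead_snps(ind, sig, ld) == ["a"]

    def test_zero_ld_leads_equal_independent(self, ld_no_ld):
        t = ld_no_ld.template.iloc[:5]
        sig = sig_frame(t["SNP"], t["CHR"], t["BP"], np.linspace(0.001, 0.005, 5))
        ind = clump_independent_significant(sig, ld_no_ld)
        assert select_lead_snps(ind, sig, ld_no_ld) == ind


class TestDefineLoci:
    def _two_group_setup(self, bps2):
        # group 1: candidates spanning [90k, 160k]; group 2 spanning bps2
        snps = ["l1", "c1a", "c1b", "l2", "c2a", "c2b"]
        chroms = [1] * 6
        bps = [100_000, 90_000, 160_000, bps2[1], bps2[0], bps2[2]]
        blocks = [corr_block(3, 0.8), corr_block(3, 0.8)]  # r^2 = 0.64 >= 0.6
        ld = custom_ld(snps, chroms, bps, blocks, [0, 0, 0, 1, 1, 1])
        allv = sig_frame(snps, chroms, bps, [0.001, 0.05, 0.05, 0.002, 0.05, 0.05])
        sig = allv[allv["FDR"] < 0.01]
        ind = clump_independent_significant(sig, ld)
        leads = select_lead_snps(ind, sig, ld)
        return define_loci(leads, ind, allv, ld)

    def test_gap_below_250kb_merges(self):
        loci = self._two_group_setup([300_000, 310_000, 330_000])  # gap 140 kb
        assert len(loci) == 1
        assert (loci[0].min_bp, loci[0].max_bp) == (90_000, 330_000)
        assert loci[0].lead_snp == "l1"  # smaller FDR

    def test_gap_exactly_250kb_not_merged(self):
        loci = self._two_group_setup([410_000, 420_000, 430_000])  # gap exactly 250 kb
        assert len(loci) == 2
        assert loci[0].max_bp == 160_000 and loci[1].min_bp == 410_000

    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_toys_match_exhaustive_oracle(self, seed):
        snps, chroms, bps, blocks, bidx, fdr, p = random_locus_toy(seed)
        ld = custom_ld(snps, chroms, bps, blocks, bidx)
        allv = sig_frame(snps, chroms, bps, fdr, p)
        sig = allv[allv["FDR"] < 0.05]
        if sig.empty:
            return
        ind = clump_independent_significant(sig, ld)
        leads = select_lead_snps(ind, sig, ld)
        got = define_loci(leads, ind, allv, ld)

        lut = lambda s1, s2: ld.r2(ld.row_of(s1), ld.row_of(s2))
        want = define_loci_oracle(leads, ind, allv.to_dict("records"), lut)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert (g.chrom, g.min_bp, g.max_bp) == (w["chrom"], w["min"], w["max"])
            assert g.lead_snp == w["lead"]
            assert set(g.independent_significant) == w["inds"]
            assert set(g.candidates) == w["cands"]

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_and_nonoverlap_invariants(self, seed):
        snps, chroms, bps, blocks, bidx, fdr, p = random_locus_toy(seed + 100)
        ld = custom_ld(snps, chroms, bps, blocks, bidx)
        allv = sig_frame(snps, chroms, bps, fdr, p)
        sig = allv[allv["FDR"] < 0.05]
        if sig.empty:
            return
        ind = clump_independent_significant(sig, ld)
        leads = select_lead_snps(ind, sig, ld)
        loci = define_loci(leads, ind, allv, ld)
        # every independent significant SNP in exactly one locus
        counts = {s: sum(s in lc.independent_significant for lc in loci) for s in ind}
        assert all(c == 1 for c in counts.values())
        # sorted loci are non-overlapping with borders inside candidate spans
        loci = sorted(loci, key=lambda l: (l.chrom, l.min_bp))
        for a, b in zip(loci, loci[1:]):
            if a.chrom == b.chrom:
                assert a.max_bp < b.min_bp
        info = allv.set_index("SNP")
        for lc in loci:
            cand_bp = info.loc[lc.candidates, "BP"]
            assert lc.min_bp == cand_bp.min() and lc.max_bp == cand_bp.max()
            assert all(info.loc[c, "FDR"] < 0.1 for c in lc.candidates)
        # pairwise r^2 constraints on leads and independents
        for i, s in enumerate(ind):
            for t in ind[:i]:
                assert lut_r2(ld, s, t) < 0.6
        for i, s in enumerate(leads):
            for t in leads[:i]:
                assert lut_r2(ld, s, t) < 0.1

    def test_determinism(self):
        snps, chroms, bps, blocks, bidx, fdr, p = random_locus_toy(7)
        ld = custom_ld(snps, chroms, bps, blocks, bidx)
        allv = sig_frame(snps, chroms, bps, fdr, p)
        sig = allv[allv["FDR"] < 0.05]
        ind = clump_independent_significant(sig, ld)
        leads = select_lead_snps(ind, sig, ld)
        a = define_loci(leads, ind, allv, ld)
        b = define_loci(leads, ind, allv, ld)
        assert a == b


def lut_r2(ld, s1, s2):
    return ld.r2(ld.row_of(s1), ld.row_of(s2))


class TestEffectDirection:
    def _pair(self, z_a, z_b, swap_b=False):
        a = make_sumstats([("rs1", 1, 100, "A", "G", z_a)])
        if swap_b:
            b = make_sumstats([("rs1", 1, 100, "G", "A", -z_b)])
        else:
            b = make_sumstats([("rs1", 1, 100, "A", "G", z_b)])
        return harmonize_pair(a, b)

    def _locus(self):
        return Locus(1, 50, 150, "rs1", 0.01, ["rs1"], ["rs1"])

    def test_same_sign_concordant(self):
        lc = assign_effect_direction(self._locus(), self._pair(4.47, 2.1))
        assert lc.concordant is True and lc.z_lead_a == pytest.approx(4.47)

    def test_opposite_sign_discordant(self):
        lc = assign_effect_direction(self._locus(), self._pair(3.0, -2.0))
        assert lc.concordant is False

    def test_zero_z_indeterminate(self):
        lc = assign_effect_direction(self._locus(), self._pair(3.0, 0.0))
        assert lc.concordant is None

    def test_allele_swapped_input_same_flag(self):
        plain = assign_effect_direction(self._locus(), self._pair(3.0, -2.0))
        swapped = assign_effect_direction(self._locus(), self._pair(3.0, -2.0, swap_b=True))
        assert plain.concordant == swapped.concordant

    def test_missing_lead_raises(self):
        pair = self._pair(1.0, 1.0)
        lc = Locus(1, 50, 150, "rs_other", 0.01, ["rs_other"], ["rs_other"])
        with pytest.raises(KeyError):
            assign_effect_direction(lc, pair)


class TestNovelty:
    def _loci(self):
        return [
            Locus(1, 100_000, 200_000, "a", 0.01, ["a"], ["a", "x"]),
            Locus(2, 100_000, 200_000, "b", 0.01, ["b"], ["b"]),
        ]

    def test_physical_overlap_not_novel(self):
        cat = KnownLociCatalog([GenomicInterval(1, 150_000, 300_000)], set())
        loci = novelty_check(self._loci(), cat)
        assert loci[0].novel is False and loci[1].novel is True

    def test_known_candidate_not_novel(self):
        cat = KnownLociCatalog([], {"x"})
        loci = novelty_check(self._loci(), cat)
        assert loci[0].novel is False and loci[1].novel is True

    def test_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        loci = [
            Locus(int(c), int(s), int(s + 50_000), f"l{i}", 0.01, [f"l{i}"],
                  [f"l{i}", f"c{i}"])
            for i, (c, s) in enumerate(zip(rng.integers(1, 4, 20),
                                           rng.integers(1, 10 ** 6, 20)))
        ]
        intervals = [GenomicInterval(int(c), int(s), int(s + 80_000))
                     for c, s in zip(rng.integers(1, 4, 10),
                                     rng.integers(1, 10 ** 6, 10))]
        known = {f"c{i}" for i in rng.integers(0, 20, 5)}
        got = novelty_check(loci, KnownLociCatalog(intervals, known))
        for lc in got:
            overlap = any(
                iv.chrom == lc.chrom and lc.min_bp <= iv.end and lc.max_bp >= iv.start
                for iv in intervals
            )
            has_known = any(c in known for c in lc.candidates)
            assert lc.novel == (not overlap and not has_known)


class TestLocusTable:
    def test_columns_and_nearest_gene(self):
        loci = [Locus(1, 90_000, 160_000, "l1", 0.001, ["l1"], ["l1"],
                      z_lead_a=2.0, z_lead_b=1.0, concordant=True, novel=False,
                      lead_bp=100_000)]
        genes = [GenomicInterval(1, 95_000, 120_000, "GENE1"),
                 GenomicInterval(1, 500_000, 600_000, "GENE2")]
        df = locus_table(loci, "depression~CAD", gene_bed=genes)
        assert df.loc[0, "NEAREST_GENE"] == "GENE1"
        assert df.loc[0, "PHENOTYPE_PAIR"] == "depression~CAD"
        assert list(df.columns)[:4] == ["CHR", "LEAD_SNP", "MINBP", "MAXBP"]
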