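"""FUMA-protocol genomic locus definition from per-variant FDR values.

Pipeline: greedy clumping of significant variants at r^2 < 0.6 (independent
significant SNPs), a second pass at r^2 < 0.1 (lead SNPs), candidate
collection (FDR < 0.1 and r^2 >= 0.6 with an independent significant SNP),
per-lead candidate spans, iterative merging of spans on the same chromosome
closer than 250 kb (strict), effect-direction assignment from the lead SNP's
z-scores in the two harmonized GWAS, and a novelty check against a catalog of
known loci.  Coordinates are 1-based inclusive; the clumping order is
ascending FDR with ties broken by ascending p, bp, then variant id, so the
whole pipeline is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDReference
from .sumstats import GenomicInterval, PairedSumstats

__all__ = [
    "Locus",
    "KnownLociCatalog",
    "clump_independent_significant",
    "select_lead_snps",
    "define_loci",
    "assign_effect_direction",
    "novelty_check",
    "locus_table",
]


@dataclass
class Locus:
    """A distinct genomic risk locus (1-based inclusive borders)."""

    chrom: int
    min_bp: int
    max_bp: int
    lead_snp: str
    lead_fdr: float
    independent_significant: list
    candidates: list
    z_lead_a: float | None = None
    z_lead_b: float | None = None
    concordant: bool | None = None   # None = indeterminate (zero z) or unset
    novel: bool | None = None
    lead_bp: int | None = None


@dataclass
class KnownLociCatalog:
    """Previously reported loci: intervals plus known associated SNP ids."""

    intervals: list = field(default_factory=list)
    known_snps: set = field(default_factory=set)


def _order(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["FDR", "P", "BP", "SNP"], kind="mergesort")


def _greedy_clump(df: pd.DataFrame, ld: LDReference, r2_threshold: float) -> list[str]:
    """Greedy selection in (FDR, P, BP, SNP) order; a variant is retained iff
    its r^2 with every already retained variant is below the threshold.
    Variants absent from the LD reference are treated as independent."""
    kept: list[str] = []
    kept_rows: list[int] = []
    for snp in _order(df)["SNP"]:
        try:
            row = ld.row_of(snp)
        except KeyError:
            warnings.warn(f"{snp} absent from LD reference; treated as independent",
                          stacklevel=3)
            kept.append(snp)
            kept_rows.append(-1)
            continue
        if all(kr == -1 or ld.r2(row, kr) < r2_threshold for kr in kept_rows):
            kept.append(snp)
            kept_rows.append(row)
    return kept


def clump_independent_significant(significant: pd.DataFrame, ld: LDReference,
                                  r2_threshold: float = 0.6) -> list[str]:
    """Independent significant SNPs: greedy clumping at r^2 < 0.6.

    ``significant`` needs columns SNP, BP, FDR, P (the FDR is the cond- or
    conjFDR the discovery set was defined with).
    """
    return _greedy_clump(significant, ld, r2_threshold)


def select_lead_snps(independent: list[str], significant: pd.DataFrame,
                     ld: LDReference, r2_threshold: float = 0.1) -> list[str]:
    """Lead SNPs: the independent significant SNPs re-clumped at r^2 < 0.1."""
    sub = significant[significant["SNP"].isin(independent)]
    return _greedy_clump(sub, ld, r2_threshold)


def define_loci(
    leads: list[str],
    independent: list[str],
    all_variants: pd.DataFrame,
    ld: LDReference,
    merge_distance: int = 250_000,
    candidate_fdr: float = 0.1,
    candidate_r2: float = 0.6,
) -> list[Locus]:
    """Merge lead-SNP LD blocks into distinct loci.

    Candidates are all variants with FDR < ``candidate_fdr`` and r^2 >=
    ``candidate_r2`` with at least one independent significant SNP.  Each
    independent significant SNP is attached to the retained lead it is in
    strongest LD with; each lead's block spans its candidates' bp range;
    same-chromosome blocks with a gap < ``merge_distance`` (strict) are merged
    iteratively to a fixed point.  The merged locus lead is the member lead
    with the smallest FDR.

    ``all_variants`` needs columns SNP, CHR, BP, FDR, P.
    """
    av = all_variants.set_index("SNP")
    ind_rows = {s: _safe_row(ld, s) for s in independent}
    lead_rows = {s: _safe_row(ld, s) for s in leads}

    # attach each independent significant SNP to its strongest retained lead
    lead_of: dict[str, str] = {}
    for s in independent:
        rs = ind_rows[s]
        best_lead, best_r2 = None, -1.0
        for l in leads:
            rl = lead_rows[l]
            r2 = 1.0 if l == s else (ld.r2(rs, rl) if rs >= 0 and rl >= 0 else 0.0)
            if r2 > best_r2:
                best_lead, best_r2 = l, r2
        lead_of[s] = best_lead

    # candidate variants per independent significant SNP
    fdr_ok = all_variants[all_variants["FDR"] < candidate_fdr]
    cand_rows = ld.rows_of(
        [s for s in fdr_ok["SNP"] if _safe_row(ld, s) >= 0]
    ) if len(fdr_ok) else np.array([], dtype=np.int64)
    cand_snps = [s for s in fdr_ok["SNP"] if _safe_row(ld, s) >= 0]

    cands_of_lead: dict[str, set] = {l: set() for l in leads}
    for s in independent:
        rs = ind_rows[s]
        lead = lead_of[s]
        cands_of_lead[lead].add(s)
        if rs < 0:
            continue
        for snp, row in zip(cand_snps, cand_rows):
            if ld.r2(rs, int(row)) >= candidate_r2:
                cands_of_lead[lead].add(snp)

    # initial per-lead blocks
    blocks = []
    for l in leads:
        cands = cands_of_lead[l]
        bps = [int(av.loc[c, "BP"]) for c in cands]
        chrom = int(av.loc[l, "CHR"])
        inds = [s for s in independent if lead_of[s] == l]
        blocks.append(
            Locus(chrom, min(bps), max(bps), l, float(av.loc[l, "FDR"]),
                  inds, sorted(cands), lead_bp=int(av.loc[l, "BP"]))
        )

    # iterative merge to fixed point
    blocks.sort(key=lambda b: (b.chrom, b.min_bp, b.max_bp))
    changed = True
    while changed:
        changed = False
        merged: list[Locus] = []
        for b in blocks:
            if merged and merged[-1].chrom == b.chrom and \
                    b.min_bp - merged[-1].max_bp < merge_distance:
                m = merged[-1]
                better = b if b.lead_fdr < m.lead_fdr else m
                merged[-1] = Locus(
                    m.chrom, min(m.min_bp, b.min_bp), max(m.max_bp, b.max_bp),
                    better.lead_snp, better.lead_fdr,
                    sorted(set(m.independent_significant) | set(b.independent_significant),
                           key=lambda s: int(av.loc[s, "BP"])),
                    sorted(set(m.candidates) | set(b.candidates)),
                    lead_bp=better.lead_bp,
                )
                changed = True
            else:
                merged.append(b)
        blocks = merged
    return blocks


def _safe_row(ld: LDReference, snp: str) -> int:
    try:
        return ld.row_of(snp)
    except KeyError:
        return -1


def assign_effect_direction(locus: Locus, pair: PairedSumstats) -> Locus:
    """Set the concordance flag by comparing the lead SNP's z-scores.

    ``concordant`` is True when sign(Z_A) == sign(Z_B) at the lead SNP, None
    (indeterminate) if either z is exactly zero; indeterminate loci are
    excluded from concordance counts downstream.
    """
    t = pair.table.set_index("SNP")
    if locus.lead_snp not in t.index:
        raise KeyError(f"lead SNP {locus.lead_snp} missing from harmonized pair")
    za = float(t.loc[locus.lead_snp, "Z_A"])
    zb = float(t.loc[locus.lead_snp, "Z_B"])
    locus.z_lead_a = za
    locus.z_lead_b = zb
    locus.concordant = None if za == 0.0 or zb == 0.0 else (za > 0) == (zb > 0)
    return locus


def novelty_check(loci: list[Locus], catalog: KnownLociCatalog) -> list[Locus]:
    """Flag loci as novel: no physical overlap with any catalog interval AND
    no candidate SNP present in the catalog's known-SNP set."""
    for locus in loci:
        overlaps = any(
            iv.overlaps(locus.chrom, locus.min_bp, locus.max_bp)
            for iv in catalog.intervals
        )
        known_cand = bool(set(locus.candidates) & catalog.known_snps)
        locus.novel = not overlaps and not known_cand
    return loci


def locus_table(loci: list[Locus], phenotype_pair: str = "",
                gene_bed: list[GenomicInterval] | None = None) -> pd.DataFrame:
    """Locus table mirroring the published format (one row per locus).

    When ``gene_bed`` intervals are supplied, the nearest gene is the labelled
    interval containing the lead SNP or, failing that, the closest by bp.
    """
    rows = []
    for lc in sorted(loci, key=lambda l: (l.chrom, l.min_bp)):
        gene = ""
        if gene_bed:
            lead_bp = lc.lead_bp if lc.lead_bp is not None else (lc.min_bp + lc.max_bp) // 2
            same = [g for g in gene_bed if g.chrom == lc.chrom]
            if same:
                gene = min(
                    same,
                    key=lambda g: max(g.start - lead_bp, lead_bp - g.end, 0),
                ).label
        rows.append(
            (lc.chrom, lc.lead_snp, lc.min_bp, lc.max_bp, gene,
             lc.z_lead_a, lc.z_lead_b, lc.concordant, lc.novel, phenotype_pair)
        )
    return pd.DataFrame(
        rows,
        columns=["CHR", "LEAD_SNP", "MINBP", "MAXBP", "NEAREST_GENE",
                 "Z_A", "Z_B", "CONCORDANT", "NOVEL", "PHENOTYPE_PAIR"],
    )
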