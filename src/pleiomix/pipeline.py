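"""End-to-end discovery pipeline: harmonized pair -> FDR -> distinct loci."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fdr import CondFdrAnalysis, FdrConfig, FdrResults
from .ld import LDReference
from .loci import (
    Locus,
    assign_effect_direction,
    clump_independent_significant,
    define_loci,
    select_lead_snps,
)
from .sumstats import PairedSumstats, apply_exclusion_regions

__all__ = ["DiscoveryConfig", "DiscoveryResults", "discover_shared_loci"]


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds of the discovery stage (defaults follow the standard
    cond/conjFDR protocol: condFDR < 0.01, conjFDR < 0.05, candidates at
    FDR < 0.1 and r^2 >= 0.6, leads at r^2 < 0.1, 250 kb locus merging)."""

    cond_threshold: float = 0.01
    conj_threshold: float = 0.05
    candidate_fdr: float = 0.1
    clump_r2: float = 0.6
    lead_r2: float = 0.1
    merge_distance: int = 250_000
    exclusion_regions: tuple = ()
    fdr: FdrConfig = field(default_factory=FdrConfig)


@dataclass
class DiscoveryResults:
    """Everything the discovery stage produced, loci keyed by discovery rule."""

    fdr: FdrResults
    loci_conj: list
    loci_cond_ab: list
    loci_cond_ba: list


def _loci_for(table: pd.DataFrame, fdr_col: str, p_col: str, mask, ld,
              cfg: DiscoveryConfig, pair: PairedSumstats) -> list[Locus]:
    sig = table.loc[mask, ["SNP", "CHR", "BP", fdr_col, p_col]].rename(
        columns={fdr_col: "FDR", p_col: "P"}
    )
    if sig.empty:
        return []
    allv = table[["SNP", "CHR", "BP", fdr_col, p_col]].rename(
        columns={fdr_col: "FDR", p_col: "P"}
    )
    independent = clump_independent_significant(sig, ld, cfg.clump_r2)
    leads = select_lead_snps(independent, sig, ld, cfg.lead_r2)
    loci = define_loci(leads, independent, allv, ld, cfg.merge_distance,
                       cfg.candidate_fdr, cfg.clump_r2)
    return [assign_effect_direction(lc, pair) for lc in loci]


def discover_shared_loci(
    pair: PairedSumstats, ld: LDReference, config: DiscoveryConfig = DiscoveryConfig()
) -> DiscoveryResults:
    """Run exclusion filtering, cond/conjFDR and locus definition.

    Returns the FDR results plus three locus lists: conjFDR loci (shared), and
    the two condFDR discovery sets (used for the overlap columns of the
    pair-summary table).
    """
    if config.exclusion_regions:
        pair = apply_exclusion_regions(pair, config.exclusion_regions)
    fdr_res = CondFdrAnalysis(pair, ld, config.fdr).fit()
    t = fdr_res.table
    sel = fdr_res.select_significant(config.cond_threshold, config.conj_threshold)
    loci_conj = _loci_for(t, "CONJFDR", "P_A", sel["conj"], ld, config, pair)
    loci_ab = _loci_for(t, "CONDFDR_AB", "P_A", sel["cond_ab"], ld, config, pair)
    loci_ba = _loci_for(t, "CONDFDR_BA", "P_B", sel["cond_ba"], ld, config, pair)
    return DiscoveryResults(fdr_res, loci_conj, loci_ab, loci_ba)
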