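"""Per-pair locus summaries and sign-concordance replication testing.

The pair summary mirrors the published table layout: number of distinct
shared loci, percentage with concordant lead-SNP effect direction, number
novel, and counts of conjFDR loci physically overlapping each condFDR locus
set.  Replication uses an en-masse sign test: the one-sided exact binomial
probability of observing at least k concordant lead-SNP effect directions out
of n under a null of 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .ld import LDReference
from .loci import Locus
from .pipeline import DiscoveryConfig, discover_shared_loci
from .simulate import GenerativeParams, TruthTable, simulate_replication, simulate_zscores

__all__ = [
    "PairSummary",
    "SignTestResult",
    "ReplicationReport",
    "round_percent",
    "summarize_pair",
    "sign_concordance_test",
    "replication_harness",
]


def round_percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to 2 decimals (published-table style)."""
    if total == 0:
        return float("nan")
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PairSummary:
    """One row of the per-trait-pair summary table."""

    trait_pair: str
    n_loci: int
    n_concordant: int
    n_indeterminate: int
    pct_concordant: float
    n_novel: int
    n_overlap_cond_ab: int
    pct_overlap_cond_ab: float
    n_overlap_cond_ba: int
    pct_overlap_cond_ba: float

    def to_row(self) -> pd.Series:
        return pd.Series(
            {
                "trait_pair": self.trait_pair,
                "n_loci": self.n_loci,
                "pct_concordant": self.pct_concordant,
                "n_novel": self.n_novel,
                "n_overlap_condAB": self.n_overlap_cond_ab,
                "pct_overlap_condAB": self.pct_overlap_cond_ab,
                "n_overlap_condBA": self.n_overlap_cond_ba,
                "pct_overlap_condBA": self.pct_overlap_cond_ba,
            }
        )


def _physically_overlaps(locus: Locus, others: list[Locus]) -> bool:
    return any(
        o.chrom == locus.chrom and locus.min_bp <= o.max_bp and locus.max_bp >= o.min_bp
        for o in others
    )


def summarize_pair(
    loci: list[Locus],
    cond_loci_ab: list[Locus] | None = None,
    cond_loci_ba: list[Locus] | None = None,
    trait_pair: str = "",
) -> PairSummary:
    """Summarize the conjFDR loci of one trait pair.

    Concordance percentages use loci with a determinate effect direction
    (zero-z leads are excluded from numerator and denominator, with the count
    reported).  Overlap columns count conjFDR loci sharing at least one base
    with any locus of the respective condFDR set.  With no loci the
    percentages are NaN (undefined), not zero.
    """
    n = len(loci)
    n_ind = sum(1 for lc in loci if lc.concordant is None)
    k = sum(1 for lc in loci if lc.concordant is True)
    n_novel = sum(1 for lc in loci if lc.novel)
    ov_ab = sum(1 for lc in loci if _physically_overlaps(lc, cond_loci_ab or []))
    ov_ba = sum(1 for lc in loci if _physically_overlaps(lc, cond_loci_ba or []))
    return PairSummary(
        trait_pair=trait_pair,
        n_loci=n,
        n_concordant=k,
        n_indeterminate=n_ind,
        pct_concordant=round_percent(k, n - n_ind),
        n_novel=n_novel,
        n_overlap_cond_ab=ov_ab,
        pct_overlap_cond_ab=round_percent(ov_ab, n),
        n_overlap_cond_ba=ov_ba,
        pct_overlap_cond_ba=round_percent(ov_ba, n),
    )


@dataclass
class SignTestResult:
    """One-sided exact binomial sign-concordance test."""

    n: int
    k: int
    p_value: float
    n_missing: int = 0  # discovery leads absent from the replication table


def sign_concordance_test(
    discovery: pd.DataFrame, replication: pd.DataFrame
) -> SignTestResult:
    """Exact one-sided binomial test of en-masse sign concordance.

    ``discovery`` needs columns SNP and Z (lead SNPs with their discovery
    z-scores); ``replication`` is a canonical single-trait sumstats frame.
    k counts leads whose z-scores agree in sign; the p-value is
    P(X >= k | X ~ Binom(n, 1/2)).  Leads absent from the replication table
    are excluded and counted in ``n_missing``.
    """
    rep = replication.set_index("SNP")["Z"]
    present = discovery["SNP"].isin(rep.index)
    n_missing = int((~present).sum())
    d = discovery.loc[present]
    zd = d["Z"].to_numpy(dtype=float)
    zr = rep.loc[d["SNP"]].to_numpy(dtype=float)
    ok = (zd != 0) & (zr != 0)
    n = int(ok.sum())
    k = int(((zd > 0) == (zr > 0))[ok].sum())
    if n == 0:
        return SignTestResult(0, 0, 1.0, n_missing)
    p = binomtest(k, n, 0.5, alternative="greater").pvalue
    return SignTestResult(n, k, float(p), n_missing)


@dataclass
class ReplicationReport:
    """End-to-end synthetic discovery + replication result."""

    n_loci: int
    sign_test: SignTestResult
    underpowered: bool
    loci: list
    summary: PairSummary


def replication_harness(
    truth: TruthTable,
    params: GenerativeParams,
    params_rep: GenerativeParams,
    ld: LDReference,
    config: DiscoveryConfig = DiscoveryConfig(),
) -> ReplicationReport:
    """Run discovery on a simulated pair, then test lead-SNP sign concordance
    against a simulated independent replication cohort of trait A.

    Mirrors the replication protocol: extract the conjFDR lead SNPs, compare
    their discovery z-scores (trait A) with the replication z-scores, and
    apply the one-sided exact binomial test.  Fewer than 10 discovered loci is
    flagged as underpowered.
    """
    pair = simulate_zscores(truth, ld, params)
    disc = discover_shared_loci(pair, ld, config)
    loci = disc.loci_conj
    leads = pd.DataFrame(
        {"SNP": [lc.lead_snp for lc in loci],
         "Z": [lc.z_lead_a for lc in loci]}
    )
    rep = simulate_replication(truth, ld, params_rep)
    test = sign_concordance_test(leads, rep) if len(loci) else SignTestResult(0, 0, 1.0)
    underpowered = len(loci) < 10
    if underpowered:
        warnings.warn(
            f"only {len(loci)} shared loci discovered; the binomial sign test "
            "is underpowered", stacklevel=2,
        )
    summary = summarize_pair(loci, disc.loci_cond_ab, disc.loci_cond_ba, "A~B")
    return ReplicationReport(len(loci), test, underpowered, loci, summary)
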