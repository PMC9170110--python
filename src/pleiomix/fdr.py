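"""Conditional and conjunctional FDR for paired GWAS summary statistics.

The conditional FDR of a variant for the primary trait, given the strength of
association with a conditioning trait, is estimated with the null proportion
set conservatively to 1:

    condFDR(p1 | p2) = p1 / F(p1 | p2),
    F(p1 | p2) = #{j : P1j <= p1, P2j <= p2} / #{j : P2j <= p2}

The empirical conditional cdf is tabulated on a 2D lattice over
(-log10 p1, -log10 p2), with counts averaged over repeated random-pruning
passes (one random representative per LD clique at r^2 >= prune_r2), bilinear
interpolation at each variant's own coordinates, capping at 1, and a
cumulative maximum along p1 to enforce monotonicity.  The conjunctional FDR
is the per-variant maximum of the two reciprocal condFDR values.

P-values are first corrected with standard genomic inflation control:
lambda = median(z^2 of pruned variants) / median(chi^2_1), z / sqrt(lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import RegularGridInterpolator

from .ld import LDReference
from .sumstats import P_FLOOR, PairedSumstats

__all__ = [
    "FdrConfig",
    "QQTable",
    "inflation_correct",
    "conditional_qq",
    "condfdr_grid",
    "conjfdr",
    "CondFdrAnalysis",
    "FdrResults",
]

#: median of the 1-df chi-square distribution
CHI2_MEDIAN = float(sps.chi2.ppf(0.5, 1))


@dataclass(frozen=True)
class FdrConfig:
    """Lattice, pruning and fallback settings for the FDR estimators."""

    x1_max: float = 30.0       # -log10 p clamp for the primary axis
    x2_max: float = 10.0       # -log10 p clamp for the conditioning axis
    step: float = 0.1
    n_prune: int = 20
    prune_r2: float | None = 0.1   # None disables pruning (all variants kept)
    min_count: int = 100       # conditioning-stratum size below which a grid
                               # column inherits the nearest coarser stratum
    qq_thresholds: tuple = (1.0, 0.1, 0.01, 0.001)
    apply_lambda_floor: bool = True   # do not deflate when lambda < 1
    monotone_p1: bool = True   # conservative envelope: cumulative maximum
                               # along p1 (raw empirical ratio when False)
    seed: int = 0

    @property
    def x1_grid(self) -> np.ndarray:
        return np.round(np.arange(0.0, self.x1_max + self.step / 2, self.step), 10)

    @property
    def x2_grid(self) -> np.ndarray:
        return np.round(np.arange(0.0, self.x2_max + self.step / 2, self.step), 10)


def _prune_masks(ld, rows, config, rng):
    """Keep masks (one per pruning pass) over the analysis variants."""
    if config.prune_r2 is None:
        return [np.ones(rows.size, dtype=bool)] * max(config.n_prune, 1)
    return [ld.random_prune(config.prune_r2, rng)[rows] for _ in range(config.n_prune)]


def inflation_correct(
    pair: PairedSumstats, ld: LDReference, config: FdrConfig = FdrConfig()
) -> tuple[PairedSumstats, float, float]:
    """Genomic inflation control on both traits.

    lambda is the mean over pruning passes of median(z^2) of the kept
    variants, divided by the 1-df chi-square median (0.45494).  Corrected
    z = z / sqrt(lambda) with p recomputed; lambda < 1 is floored at 1 unless
    the config disables the floor.
    """
    rows = ld.rows_of(pair.table["SNP"].tolist())
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(20,)))
    masks = _prune_masks(ld, rows, config, rng)

    lambdas = []
    for col in ("Z_A", "Z_B"):
        z2 = pair.table[col].to_numpy() ** 2
        lam = float(np.mean([np.median(z2[m]) for m in masks])) / CHI2_MEDIAN
        if config.apply_lambda_floor:
            lam = max(lam, 1.0)
        lambdas.append(lam)
    lam_a, lam_b = lambdas

    t = pair.table.copy()
    t["Z_A"] = t["Z_A"] / np.sqrt(lam_a)
    t["Z_B"] = t["Z_B"] / np.sqrt(lam_b)
    t["P_A"] = np.clip(2.0 * sps.norm.sf(np.abs(t["Z_A"])), P_FLOOR, 1.0)
    t["P_B"] = np.clip(2.0 * sps.norm.sf(np.abs(t["Z_B"])), P_FLOOR, 1.0)
    return PairedSumstats(t, pair.report), lam_a, lam_b


@dataclass
class QQTable:
    """Plot-ready conditional Q-Q curves (no rendering).

    One record per retained stratum: the p2 threshold, the mean number of
    stratum variants over pruning passes, and matched arrays of -log10
    nominal p1 and -log10 empirical quantile.
    """

    strata: list = field(default_factory=list)  # (threshold, n, nominal, empirical)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for thr, n, nominal, empirical in self.strata:
            for x, y in zip(nominal, empirical):
                rows.append((thr, n, x, y))
        return pd.DataFrame(rows, columns=["stratum", "n_variants",
                                           "neglog10_p_nominal", "neglog10_p_empirical"])


def conditional_qq(
    pair: PairedSumstats, ld: LDReference,
    thresholds=None, config: FdrConfig = FdrConfig(),
    condition_on: str = "B",
) -> QQTable:
    """Conditional Q-Q table of the primary trait within conditioning strata.

    For each threshold t the stratum is {j : p2_j <= t}; the empirical
    quantile of a primary p-value is rank/(count+1), averaged over random
    pruning passes.  ``condition_on="B"`` stratifies trait A's p-values by
    trait B (the mirror table comes from ``condition_on="A"``).
    Empty strata are omitted with a warning.
    """
    if condition_on not in ("A", "B"):
        raise ValueError("condition_on must be 'A' or 'B'")
    p1 = pair.table["P_A" if condition_on == "B" else "P_B"].to_numpy()
    p2 = pair.table["P_B" if condition_on == "B" else "P_A"].to_numpy()
    thresholds = tuple(thresholds) if thresholds is not None else config.qq_thresholds

    rows = ld.rows_of(pair.table["SNP"].tolist())
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(21,)))
    masks = _prune_masks(ld, rows, config, rng)

    out = QQTable()
    x1 = -np.log10(p1)
    for thr in sorted(thresholds, reverse=True):
        in_stratum_full = p2 <= thr
        if not in_stratum_full.any():
            warnings.warn(f"stratum p2 <= {thr} is empty; omitted", stacklevel=2)
            continue
        nominal = np.unique(x1[in_stratum_full])
        qbar = np.zeros_like(nominal)
        ns = []
        n_used = 0
        for m in masks:
            sel = m & in_stratum_full
            n = int(sel.sum())
            if n == 0:
                continue
            xs = np.sort(x1[sel])
            # rank = #{p1' <= p1} = #{x' >= x}
            rank = n - np.searchsorted(xs, nominal, side="left")
            qbar += rank / (n + 1)
            ns.append(n)
            n_used += 1
        if n_used == 0:
            warnings.warn(f"stratum p2 <= {thr} empty in all pruning passes; omitted",
                          stacklevel=2)
            continue
        qbar /= n_used
        out.strata.append((thr, float(np.mean(ns)), nominal, -np.log10(qbar)))
    return out


def _lattice_counts(x1, x2, x1_grid, x2_grid):
    """Cell counts of (x1, x2) on the lattice; exact node values fall in the
    cell that starts at the node (so reverse cumsums give >=-node counts)."""
    c1 = np.clip(np.digitize(x1, x1_grid) - 1, 0, x1_grid.size - 1)
    c2 = np.clip(np.digitize(x2, x2_grid) - 1, 0, x2_grid.size - 1)
    flat = np.bincount(c1 * x2_grid.size + c2, minlength=x1_grid.size * x2_grid.size)
    return flat.reshape(x1_grid.size, x2_grid.size).astype(float)


def condfdr_grid(
    p1: np.ndarray, p2: np.ndarray, keep_masks, config: FdrConfig = FdrConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """condFDR lattice and the averaged conditional-cdf lattice.

    Returns ``(cf, F)``, both shaped (len(x1_grid), len(x2_grid)).  Counts are
    averaged over the supplied pruning keep-masks; conditioning strata smaller
    than ``min_count`` inherit the nearest valid coarser (less stringent)
    stratum; condFDR is capped at 1 and made nondecreasing in p1 by a
    cumulative maximum along the p1 axis.
    """
    x1g, x2g = config.x1_grid, config.x2_grid
    x1 = np.clip(-np.log10(np.clip(p1, P_FLOOR, 1.0)), 0.0, config.x1_max)
    x2 = np.clip(-np.log10(np.clip(p2, P_FLOOR, 1.0)), 0.0, config.x2_max)

    n12 = np.zeros((x1g.size, x2g.size))
    n2 = np.zeros(x2g.size)
    for m in keep_masks:
        h = _lattice_counts(x1[m], x2[m], x1g, x2g)
        # reverse 2D cumsum -> #{x1 >= node1, x2 >= node2}
        s = np.flip(np.cumsum(np.flip(np.cumsum(np.flip(h, 0), axis=0), 1), axis=1), (0, 1))
        n12 += s
        n2 += s[0, :]
    n12 /= len(keep_masks)
    n2 /= len(keep_masks)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(n2 > 0, n12 / n2, 0.0)

    # small-stratum fallback: inherit nearest coarser valid column
    last_valid = 0
    for k2 in range(x2g.size):
        if n2[k2] >= config.min_count:
            last_valid = k2
        elif k2 > 0:
            F[:, k2] = F[:, last_valid]

    p1_nodes = 10.0 ** (-x1g)
    with np.errstate(divide="ignore", invalid="ignore"):
        cf = np.where(F > 0, p1_nodes[:, None] / F, 1.0)
    cf = np.minimum(cf, 1.0)
    if config.monotone_p1:
        # condFDR nondecreasing in p1 == nonincreasing in -log10 p1
        cf = np.flip(np.maximum.accumulate(np.flip(cf, 0), axis=0), 0)
    return cf, F


def _interpolate(cf, p1, p2, config) -> np.ndarray:
    x1 = np.clip(-np.log10(np.clip(p1, P_FLOOR, 1.0)), 0.0, config.x1_max)
    x2 = np.clip(-np.log10(np.clip(p2, P_FLOOR, 1.0)), 0.0, config.x2_max)
    itp = RegularGridInterpolator((config.x1_grid, config.x2_grid), cf, method="linear")
    return np.clip(itp(np.column_stack([x1, x2])), P_FLOOR, 1.0)


def conjfdr(cond_ab: np.ndarray, cond_ba: np.ndarray) -> np.ndarray:
    """Conjunctional FDR: elementwise maximum of the two condFDR vectors."""
    cond_ab = np.asarray(cond_ab)
    cond_ba = np.asarray(cond_ba)
    if cond_ab.shape != cond_ba.shape:
        raise ValueError(f"length mismatch: {cond_ab.shape} vs {cond_ba.shape}")
    return np.maximum(cond_ab, cond_ba)


@dataclass
class FdrResults:
    """Per-variant cond/conjFDR values plus the lattices they came from."""

    table: pd.DataFrame
    grid_ab: np.ndarray
    grid_ba: np.ndarray
    cdf_ab: np.ndarray
    cdf_ba: np.ndarray
    lambda_a: float
    lambda_b: float
    config: FdrConfig

    def select_significant(
        self, cond_threshold: float = 0.01, conj_threshold: float = 0.05
    ) -> dict:
        """Boolean masks of the discovery sets (strict inequalities)."""
        t = self.table
        return {
            "cond_ab": (t["CONDFDR_AB"] < cond_threshold).to_numpy(),
            "cond_ba": (t["CONDFDR_BA"] < cond_threshold).to_numpy(),
            "conj": (t["CONJFDR"] < conj_threshold).to_numpy(),
        }

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def grid_to_tsv(self, path, direction: str = "AB") -> None:
        grid = self.grid_ab if direction == "AB" else self.grid_ba
        df = pd.DataFrame(grid, index=self.config.x1_grid, columns=self.config.x2_grid)
        df.index.name = "neglog10_p1\\neglog10_p2"
        df.to_csv(path, sep="\t")


class CondFdrAnalysis:
    """Model object for the paired cond/conjFDR analysis.

    ``fit()`` applies genomic inflation control (unless disabled), estimates
    both condFDR directions on the lattice, interpolates per-variant values
    and returns an :class:`FdrResults`.
    """

    def __init__(self, pair: PairedSumstats, ld: LDReference,
                 config: FdrConfig = FdrConfig()):
        self.pair = pair
        self.ld = ld
        self.config = config

    def fit(self, correct_inflation: bool = True) -> FdrResults:
        cfg = self.config
        if correct_inflation:
            pair, lam_a, lam_b = inflation_correct(self.pair, self.ld, cfg)
        else:
            pair, lam_a, lam_b = self.pair, 1.0, 1.0

        rows = self.ld.rows_of(pair.table["SNP"].tolist())
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(22,)))
        masks = _prune_masks(self.ld, rows, cfg, rng)

        pa = pair.table["P_A"].to_numpy()
        pb = pair.table["P_B"].to_numpy()
        grid_ab, cdf_ab = condfdr_grid(pa, pb, masks, cfg)
        grid_ba, cdf_ba = condfdr_grid(pb, pa, masks, cfg)
        cond_ab = _interpolate(grid_ab, pa, pb, cfg)
        cond_ba = _interpolate(grid_ba, pb, pa, cfg)

        t = pair.table[["SNP", "CHR", "BP", "Z_A", "Z_B", "P_A", "P_B"]].copy()
        t["CONDFDR_AB"] = cond_ab
        t["CONDFDR_BA"] = cond_ba
        t["CONJFDR"] = conjfdr(cond_ab, cond_ba)
        return FdrResults(t, grid_ab, grid_ba, cdf_ab, cdf_ba, lam_a, lam_b, cfg)
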