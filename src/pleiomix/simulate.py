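"""Synthetic paired-GWAS generator under the bivariate causal mixture model.

Ground truth: each template variant is independently null, causal for trait A
only, for trait B only, or for both (the shared component, where the two
effects are bivariate normal with correlation rho_beta).  Observed z-scores
follow the standard summary-statistic sampling model: per LD block with signed
correlation matrix R,

    z_A = sqrt(nA) * R @ beta_A + eps_A,

with noise Cov(eps_A) = sigma0_A^2 * R, Cov(eps_B) = sigma0_B^2 * R and
Cov(eps_A, eps_B) = rho0 * sigma0_A * sigma0_B * R (rho0 models sample
overlap, sigma0^2 > 1 models residual inflation).  A replication cohort
shares beta_A and draws fresh noise.

Default parameters are the desk-scale study conditions used throughout the
test harness: a 30 000-variant template, n = 50 000 per GWAS, polygenicity of
order 1% and per-causal variance 5e-4 (so n * sigma_b^2 = 25, i.e. a clearly
powered GWAS with h2 of roughly 0.15 at pi = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ld import LDReference
from .sumstats import P_FLOOR, PairedSumstats

__all__ = [
    "GenerativeParams",
    "TruthTable",
    "simulate_effects",
    "simulate_zscores",
    "simulate_replication",
    "simulate_pair",
]

COMPONENTS = ("null", "A_only", "B_only", "shared")

# spawn keys of the documented seed-splitting scheme: each stage derives an
# independent stream from the single global seed, so stages are reproducible
# in isolation.
_STAGE_EFFECTS = 0
_STAGE_ZSCORES = 1
_STAGE_REPLICATION = 2


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the four-component generative model.

    pi1/pi2/pi12 are the template fractions of A-only, B-only and shared
    causal variants (pi0 = 1 - pi1 - pi2 - pi12 is null); sigma_b_*2 the
    per-causal effect variances; rho_beta the effect correlation within the
    shared component; rho0 the residual cross-trait z correlation (sample
    overlap); sigma0_*2 residual variance inflation (1 = none).
    """

    M: int = 30_000
    pi1: float = 0.005
    pi2: float = 0.005
    pi12: float = 0.005
    sigma_b_A2: float = 5e-4
    sigma_b_B2: float = 5e-4
    rho_beta: float = 0.8
    rho0: float = 0.0
    sigma0_A2: float = 1.0
    sigma0_B2: float = 1.0
    nA: int = 50_000
    nB: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        pi0 = 1.0 - self.pi1 - self.pi2 - self.pi12
        if min(self.pi1, self.pi2, self.pi12) < 0 or pi0 < 0:
            raise ValueError("mixture weights must be nonnegative and sum to <= 1")
        if min(self.sigma_b_A2, self.sigma_b_B2, self.sigma0_A2, self.sigma0_B2) <= 0:
            raise ValueError("variances must be positive")
        if not (-1 <= self.rho_beta <= 1 and -1 <= self.rho0 <= 1):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1 - self.pi2 - self.pi12


@dataclass
class TruthTable:
    """Latent per-variant ground truth: component label and true effects."""

    component: np.ndarray  # str labels from COMPONENTS
    beta_A: np.ndarray
    beta_B: np.ndarray

    def to_frame(self, ld: LDReference) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": ld.template["SNP"],
                "component": self.component,
                "beta_A": self.beta_A,
                "beta_B": self.beta_B,
            }
        )


def simulate_effects(params: GenerativeParams, ld: LDReference) -> TruthTable:
    """Draw per-variant component labels and true effect sizes.

    Labels are i.i.d. categorical(pi0, pi1, pi2, pi12); effects are normal with
    the component's variance, and bivariate normal with correlation rho_beta in
    the shared component.  Deterministic given ``params.seed``.
    """
    if params.M != ld.n_variants:
        raise ValueError(f"params.M={params.M} != template size {ld.n_variants}")
    rng = _stage_rng(params.seed, _STAGE_EFFECTS)
    M = params.M
    u = rng.choice(4, size=M, p=[params.pi0, params.pi1, params.pi2, params.pi12])
    component = np.array(COMPONENTS)[u]

    beta_A = np.zeros(M)
    beta_B = np.zeros(M)
    ia = u == 1
    ib = u == 2
    ish = u == 3
    beta_A[ia] = rng.normal(0.0, np.sqrt(params.sigma_b_A2), ia.sum())
    beta_B[ib] = rng.normal(0.0, np.sqrt(params.sigma_b_B2), ib.sum())
    n_sh = int(ish.sum())
    if n_sh:
        cov = np.array(
            [
                [params.sigma_b_A2,
                 params.rho_beta * np.sqrt(params.sigma_b_A2 * params.sigma_b_B2)],
                [params.rho_beta * np.sqrt(params.sigma_b_A2 * params.sigma_b_B2),
                 params.sigma_b_B2],
            ]
        )
        both = rng.multivariate_normal(np.zeros(2), cov, size=n_sh, method="cholesky")
        beta_A[ish] = both[:, 0]
        beta_B[ish] = both[:, 1]
    return TruthTable(component, beta_A, beta_B)


def _block_chol(block: np.ndarray, bid: int) -> np.ndarray:
    for jitter in (0.0, 1e-10, 1e-8):
        try:
            return np.linalg.cholesky(block + jitter * np.eye(block.shape[0]))
        except np.linalg.LinAlgError:
            continue
    raise RuntimeError(f"LD block {bid} is not positive semi-definite after jitter")


def simulate_zscores(
    truth: TruthTable, ld: LDReference, params: GenerativeParams
) -> PairedSumstats:
    """Generate the paired z-score/p-value table from ground-truth effects.

    Per block: E[z] = sqrt(n) * R @ beta, noise with covariance proportional to
    R as described in the module docstring.  p = 2*Phi(-|z|).  Deterministic
    given ``params.seed``.
    """
    rng = _stage_rng(params.seed, _STAGE_ZSCORES)
    zA, zB = _draw_pair_z(truth.beta_A, truth.beta_B, ld, params, rng)
    return _as_paired(zA, zB, ld, params)


def _draw_pair_z(beta_A, beta_B, ld, params, rng):
    M = ld.n_variants
    zA = np.empty(M)
    zB = np.empty(M)
    s0A = np.sqrt(params.sigma0_A2)
    s0B = np.sqrt(params.sigma0_B2)
    c = params.rho0
    for bid, block in enumerate(ld.blocks):
        idx = np.flatnonzero(ld.block_index == bid)
        L = _block_chol(block, bid)
        x1 = L @ rng.standard_normal(idx.size)
        x2 = L @ rng.standard_normal(idx.size)
        meanA = np.sqrt(params.nA) * (block @ beta_A[idx])
        meanB = np.sqrt(params.nB) * (block @ beta_B[idx])
        zA[idx] = meanA + s0A * x1
        zB[idx] = meanB + s0B * (c * x1 + np.sqrt(max(0.0, 1.0 - c * c)) * x2)
    return zA, zB


def _as_paired(zA, zB, ld, params) -> PairedSumstats:
    t = ld.template
    table = pd.DataFrame(
        {
            "SNP": t["SNP"].to_numpy(),
            "CHR": t["CHR"].to_numpy(),
            "BP": t["BP"].to_numpy(),
            "A1": "A",
            "A2": "G",
            "Z_A": zA,
            "Z_B": zB,
            "P_A": np.clip(2.0 * sps.norm.sf(np.abs(zA)), P_FLOOR, 1.0),
            "P_B": np.clip(2.0 * sps.norm.sf(np.abs(zB)), P_FLOOR, 1.0),
            "N_A": params.nA,
            "N_B": params.nB,
        }
    )
    return PairedSumstats(table)


def simulate_replication(
    truth: TruthTable, ld: LDReference, params_rep: GenerativeParams
) -> pd.DataFrame:
    """Trait-A summary statistics for an independent replication cohort.

    Same true effects ``truth.beta_A``, new sample size ``params_rep.nA`` and
    fresh noise (independent of the discovery stage's stream).  Returns a
    canonical single-trait sumstats frame.
    """
    rng = _stage_rng(params_rep.seed, _STAGE_REPLICATION)
    M = ld.n_variants
    z = np.empty(M)
    s0 = np.sqrt(params_rep.sigma0_A2)
    for bid, block in enumerate(ld.blocks):
        idx = np.flatnonzero(ld.block_index == bid)
        L = _block_chol(block, bid)
        z[idx] = np.sqrt(params_rep.nA) * (block @ truth.beta_A[idx]) + s0 * (
            L @ rng.standard_normal(idx.size)
        )
    t = ld.template
    return pd.DataFrame(
        {
            "SNP": t["SNP"].to_numpy(),
            "CHR": t["CHR"].to_numpy(),
            "BP": t["BP"].to_numpy(),
            "A1": "A",
            "A2": "G",
            "Z": z,
            "P": np.clip(2.0 * sps.norm.sf(np.abs(z)), P_FLOOR, 1.0),
            "N": params_rep.nA,
        }
    )


def simulate_pair(
    params: GenerativeParams, ld: LDReference
) -> tuple[PairedSumstats, TruthTable]:
    """Convenience: draw truth and z-scores in one call."""
    truth = simulate_effects(params, ld)
    return simulate_zscores(truth, ld, params), truth
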