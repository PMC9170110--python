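"""Univariate and bivariate Gaussian causal mixture models for GWAS z-scores.

The univariate model treats each template variant as causal with probability
pi, with per-causal effect variance sigma_b^2 and residual inflation
sigma0^2.  For variant j with K_j LD partners (r^2 >= r2_min, self included),
the marginal likelihood of its z-score is a mixture of centred Gaussians over
the variant's own causal status s (exact, full weight r^2 = 1) and the causal
count m of its K_j - 1 neighbours at their mean squared correlation
r2neigh_j:

    L_j = sum_{s, m} Bern(s; pi) Binom(m; K_j - 1, pi)
          * N(z_j; 0, (s + m * r2neigh_j) * n_j * sigma_b^2 + sigma0^2)

The bivariate model adds a four-component architecture (null, A-only, B-only,
shared) with effect correlation rho_beta in the shared component and residual
cross-trait correlation rho0 (sample overlap); the self status becomes a
four-way category and neighbour counts are multinomial.  Counts above m_max
are truncated and the weights renormalised.

Summing the exact per-partner LD convolution is replaced by the count/mean-r^2
moment approximation above: a deliberate simplification that keeps desk-scale
fits tractable while preserving the model family.  Per-variant likelihood
contributions are weighted by inclusion frequency under repeated random
pruning at r^2 = 0.8 so dense LD regions do not dominate.

Usage follows the Model/Results convention::

    fit_a = UnivariateMixture(pair, ld, trait="A").fit()
    fit_b = UnivariateMixture(pair, ld, trait="B").fit()
    biv = BivariateMixture(pair, ld, fit_a, fit_b).fit()
    biv.overlap().dice
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from ._kernels import (
    bivariate_loglik_pervariant,
    bivariate_nll_slots,
    univariate_loglik_pervariant,
    univariate_nll,
)
from .ld import LDReference
from .sumstats import PairedSumstats

__all__ = [
    "MixtureConfig",
    "UnivariateMixture",
    "UnivariateMixtureResults",
    "BivariateMixture",
    "BivariateMixtureResults",
    "OverlapSummary",
    "overlap_from_counts",
    "concordant_fraction",
    "model_fit_diagnostics",
    "MixtureDiagnostics",
]

_PI_EPS = 1e-12


@dataclass(frozen=True)
class MixtureConfig:
    """Tuning knobs shared by the mixture fits.

    m_max truncates the partner causal-count sum (binomial tails are
    negligible at realistic pi); r2_min bounds which LD partners enter the
    variance term; prune_r2/n_prune control the random-pruning weights;
    se_iterations/se_subsample control the repeated subsampled refits used for
    standard errors; tol is the convergence tolerance on transformed
    parameters.
    """

    m_max: int = 20
    r2_min: float = 0.05
    prune_r2: float = 0.8
    n_prune: int = 20
    tol: float = 1e-6
    max_fev: int = 600
    se_iterations: int = 20
    se_subsample: float = 0.5
    seed: int = 0
    min_variants: int = 5000


@lru_cache(maxsize=8)
def _compositions(m_max: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (m1, m2, m12) with m1+m2+m12 <= m_max."""
    trip = [
        (m1, m2, m12)
        for mtot in range(m_max + 1)
        for m1 in range(mtot + 1)
        for m2 in range(mtot - m1 + 1)
        for m12 in (mtot - m1 - m2,)
    ]
    arr = np.asarray(trip, dtype=np.int64)
    return arr[:, 0], arr[:, 1], arr[:, 2]


def _biv_slot_tables(slots, pi1, pi2, pi12, sbA2, sbB2, s0A2, s0B2,
                     rho_beta, rho0, m_max):
    """Precomputed Gaussian config constants per (K, r2neigh, nA, nB) slot.

    Configs are the product of the variant's own component (null, A-only,
    B-only, shared; full weight r^2 = 1) with the neighbour causal-count
    triples over K-1 trials at the mean neighbour weight.  Each config's
    mixture weight (entries below 1e-18 of the maximum dropped from the
    numerator only; the normaliser keeps the full truncated total) and
    bivariate normal constants are folded into the exponential-family form
    the kernel evaluates.
    """
    m1, m2, m12 = _compositions(m_max)
    mtot = m1 + m2 + m12
    pi0f = max(1.0 - pi1 - pi2 - pi12, 0.0)
    probs = np.array([pi0f, pi1, pi2, pi12])
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    # configs whose count is positive for a zero-probability component are
    # excluded by `valid`; zero the -inf there to avoid 0*inf in the einsums
    lp_safe = np.where(np.isfinite(lp), lp, 0.0)
    cross_b = np.sqrt(sbA2 * sbB2) * rho_beta
    cov0 = rho0 * np.sqrt(s0A2 * s0B2)
    # self-component indicators: causal for A, for B, shared
    selfA = np.array([0.0, 1.0, 0.0, 1.0])
    selfB = np.array([0.0, 0.0, 1.0, 1.0])
    self12 = np.array([0.0, 0.0, 0.0, 1.0])
    Wc, Ac, Bc, Cc, offsets, inv_wsum = [], [], [], [], [0], []
    for K, r2neigh, nA, nB in slots:
        kn = int(K) - 1
        m0 = kn - mtot
        valid = m0 >= 0
        for m, p in zip((m1, m2, m12, m0), (pi1, pi2, pi12, pi0f)):
            if p == 0.0:
                valid &= m == 0
        v = valid
        lwn = np.full(m1.shape, -np.inf)
        lwn[v] = (
            gammaln(kn + 1)
            - gammaln(m1[v] + 1) - gammaln(m2[v] + 1)
            - gammaln(m12[v] + 1) - gammaln(m0[v] + 1)
            + m1[v] * lp_safe[1] + m2[v] * lp_safe[2]
            + m12[v] * lp_safe[3] + m0[v] * lp_safe[0]
        )
        c0_ok = probs > 0.0
        lw = lwn[None, :] + np.where(c0_ok, lp, -np.inf)[:, None]  # (4, n_cfg)
        lw[1:, mtot + 1 > m_max] = -np.inf  # m_max caps the total causal count
        w = np.exp(lw)
        total = float(w.sum())
        keep = w > w.max() * 1e-18
        sA = np.broadcast_to(selfA[:, None], w.shape)[keep]
        sB = np.broadcast_to(selfB[:, None], w.shape)[keep]
        s12 = np.broadcast_to(self12[:, None], w.shape)[keep]
        mA = np.broadcast_to((m1 + m12)[None, :], w.shape)[keep]
        mB = np.broadcast_to((m2 + m12)[None, :], w.shape)[keep]
        mS = np.broadcast_to(m12[None, :], w.shape)[keep]
        varA = (sA + mA * r2neigh) * nA * sbA2 + s0A2
        varB = (sB + mB * r2neigh) * nB * sbB2 + s0B2
        cov = (s12 + mS * r2neigh) * np.sqrt(nA * nB) * cross_b + cov0
        det = varA * varB - cov * cov
        ok = det > 1e-300
        det = np.where(ok, det, 1.0)
        Wc.append(np.where(ok, w[keep] / (2.0 * np.pi * np.sqrt(det)), 0.0))
        Ac.append(np.where(ok, -0.5 * varB / det, 0.0))
        Bc.append(np.where(ok, -0.5 * varA / det, 0.0))
        Cc.append(np.where(ok, cov / det, 0.0))
        offsets.append(offsets[-1] + int(keep.sum()))
        inv_wsum.append(1.0 / total if total > 0 else 0.0)
    return (
        np.concatenate(Wc), np.concatenate(Ac), np.concatenate(Bc),
        np.concatenate(Cc), np.asarray(offsets, dtype=np.int64),
        np.asarray(inv_wsum),
    )


def _neighbor_stats(ld: LDReference, rows: np.ndarray, r2_min: float):
    """Partner count (self included) and mean neighbour r^2 per variant."""
    K_all, r2bar_all = ld.partner_stats(r2_min)
    K = K_all[rows]
    r2bar = r2bar_all[rows]
    with np.errstate(invalid="ignore"):
        r2neigh = np.where(K > 1, (K * r2bar - 1.0) / np.maximum(K - 1, 1), 0.0)
    return K, np.clip(r2neigh, 0.0, 1.0)


def _logfact(n: int) -> np.ndarray:
    lf = np.zeros(n + 1)
    lf[1:] = np.cumsum(np.log(np.arange(1, n + 1)))
    return lf


def univariate_pervariant_loglik(z, n, K, r2neigh, pi, sigma_b2, sigma02, m_max=20):
    """Per-variant log-likelihood under the univariate mixture (testing hook)."""
    z = np.asarray(z, dtype=float)
    n = np.broadcast_to(np.asarray(n, dtype=float), z.shape).copy()
    K = np.asarray(K, dtype=np.int64)
    r2neigh = np.asarray(r2neigh, dtype=float)
    out = np.empty(z.shape[0])
    pi = float(np.clip(pi, _PI_EPS, 1 - _PI_EPS))
    univariate_loglik_pervariant(
        z, n, K, r2neigh, pi, sigma_b2, sigma02, m_max, _logfact(int(K.max()) + 1), out
    )
    return out


def bivariate_pervariant_loglik(
    zA, zB, nA, nB, K, r2neigh, pi1, pi2, pi12,
    sigma_b_A2, sigma_b_B2, sigma0_A2, sigma0_B2, rho_beta, rho0, m_max=20,
):
    """Per-variant log-likelihood under the bivariate mixture (testing hook)."""
    zA = np.asarray(zA, dtype=float)
    zB = np.asarray(zB, dtype=float)
    nA = np.broadcast_to(np.asarray(nA, dtype=float), zA.shape).copy()
    nB = np.broadcast_to(np.asarray(nB, dtype=float), zA.shape).copy()
    K = np.asarray(K, dtype=np.int64)
    r2neigh = np.asarray(r2neigh, dtype=float)
    out = np.empty(zA.shape[0])
    bivariate_loglik_pervariant(
        zA, zB, nA, nB, K, r2neigh, pi1, pi2, pi12,
        sigma_b_A2, sigma_b_B2, sigma0_A2, sigma0_B2, rho_beta, rho0,
        m_max, _logfact(int(K.max()) + 1), out,
    )
    return out


@dataclass
class UnivariateMixtureResults:
    """Point-normal mixture fit for one trait."""

    pi: float
    sigma_b2: float
    sigma02: float
    loglik: float
    M: int
    converged: bool
    trait: str = "A"

    @property
    def n_causal(self) -> float:
        return self.pi * self.M

    @property
    def reliable(self) -> bool:
        return self.converged

    def summary(self) -> str:
        lines = [
            f"Univariate causal mixture fit (trait {self.trait})",
            "-" * 46,
            f"template variants (M)     {self.M:>12d}",
            f"polygenicity pi           {self.pi:>12.3e}",
            f"n_causal = pi*M           {self.n_causal:>12.1f}",
            f"per-causal var sigma_b^2  {self.sigma_b2:>12.3e}",
            f"residual var sigma0^2     {self.sigma02:>12.4f}",
            f"log-likelihood            {self.loglik:>12.2f}",
            f"converged                 {str(self.converged):>12}",
        ]
        return "\n".join(lines)


class UnivariateMixture:
    """Model object for the univariate fit of one trait of a harmonized pair.

    Parameters
    ----------
    pair : PairedSumstats
        Harmonized two-trait table (only the chosen trait's columns are used).
    ld : LDReference
        Must cover every variant in ``pair``.
    trait : {"A", "B"}
    config : MixtureConfig
    """

    def __init__(self, pair: PairedSumstats, ld: LDReference, trait: str = "A",
                 config: MixtureConfig = MixtureConfig()):
        if trait not in ("A", "B"):
            raise ValueError("trait must be 'A' or 'B'")
        self.trait = trait
        self.config = config
        self.ld = ld
        rows = ld.rows_of(pair.table["SNP"].tolist())
        self.z = pair.table[f"Z_{trait}"].to_numpy(dtype=float)
        self.n = pair.table[f"N_{trait}"].to_numpy(dtype=float)
        self.K, self.r2neigh = _neighbor_stats(ld, rows, config.r2_min)
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10,)))
        self.weights = ld.prune_weights(config.prune_r2, config.n_prune, rng)[rows]
        self._logfact = _logfact(int(self.K.max()) + 1)
        if len(self.z) < config.min_variants:
            warnings.warn(
                f"only {len(self.z)} variants; mixture fits are calibrated for "
                f">= {config.min_variants}", stacklevel=2,
            )

    def _nll(self, theta: np.ndarray) -> float:
        pi = float(np.clip(expit(theta[0]), _PI_EPS, 1 - _PI_EPS))
        sb2 = float(np.exp(theta[1]))
        s02 = float(np.exp(theta[2]))
        return univariate_nll(
            self.z, self.n, self.K, self.r2neigh, self.weights,
            pi, sb2, s02, self.config.m_max, self._logfact,
        )

    def fit(self) -> UnivariateMixtureResults:
        """Maximum-likelihood fit via coarse grid start + Nelder-Mead refinement."""
        nbar = float(np.mean(self.n))
        pis = np.array([3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1])
        sb2s = np.array([1.0, 5.0, 25.0, 100.0]) / nbar
        best, best_theta = np.inf, None
        for pi in pis:
            for sb2 in sb2s:
                theta = np.array([logit(pi), np.log(sb2), 0.0])
                v = self._nll(theta)
                if v < best:
                    best, best_theta = v, theta
        res = minimize(
            self._nll, best_theta, method="Nelder-Mead",
            options={"xatol": self.config.tol, "fatol": 1e-8,
                     "maxfev": self.config.max_fev},
        )
        if not res.success:
            warnings.warn(f"univariate fit (trait {self.trait}) did not converge: "
                          f"{res.message}", stacklevel=2)
        return UnivariateMixtureResults(
            pi=float(np.clip(expit(res.x[0]), _PI_EPS, 1 - _PI_EPS)),
            sigma_b2=float(np.exp(res.x[1])),
            sigma02=float(np.exp(res.x[2])),
            loglik=-float(res.fun),
            M=self.ld.n_variants,
            converged=bool(res.success),
            trait=self.trait,
        )


@dataclass
class OverlapSummary:
    """Venn-diagram quantities derived from a bivariate fit or printed counts.

    ``n_a``/``n_b`` are the per-trait causal-variant counts (A = unique+shared,
    B likewise), ``n_shared`` the shared count; ``dice = 2*n_shared/(n_a+n_b)``.
    ``rg`` and ``concordant_fraction`` require rho_beta and are None when built
    from counts alone.
    """

    n_a: float
    n_b: float
    n_shared: float
    dice: float
    rg: float | None = None
    concordant_fraction: float | None = None


def concordant_fraction(rho_beta: float) -> float:
    """Fraction of shared causal variants with same-sign effects on both traits.

    For a centred bivariate normal with correlation rho, the orthant
    probability gives P(same sign) = 1/2 + arcsin(rho)/pi.
    """
    return 0.5 + float(np.arcsin(rho_beta)) / np.pi


def overlap_from_counts(n_a: float, n_b: float, n_shared: float,
                        rho_beta: float | None = None) -> OverlapSummary:
    """Overlap summary from causal-variant counts (e.g. published Venn numbers)."""
    if n_a + n_b == 0:
        raise ZeroDivisionError("dice undefined: n_a + n_b = 0")
    if n_shared > min(n_a, n_b) + 1e-9:
        raise ValueError("n_shared cannot exceed min(n_a, n_b)")
    dice = 2.0 * n_shared / (n_a + n_b)
    rg = cf = None
    if rho_beta is not None:
        pi_a, pi_b, pi_sh = n_a, n_b, n_shared  # scale cancels in the ratio
        rg = rho_beta * pi_sh / np.sqrt(pi_a * pi_b)
        cf = concordant_fraction(rho_beta)
    return OverlapSummary(n_a, n_b, n_shared, dice, rg, cf)


@dataclass
class BivariateMixtureResults:
    """Bivariate causal mixture fit: component weights and correlations."""

    pi1: float
    pi2: float
    pi12: float
    rho_beta: float
    rho0: float
    loglik: float
    M: int
    converged: bool
    se: dict | None = None
    fit_a: UnivariateMixtureResults | None = field(default=None, repr=False)
    fit_b: UnivariateMixtureResults | None = field(default=None, repr=False)

    @property
    def pi_a(self) -> float:
        return self.pi1 + self.pi12

    @property
    def pi_b(self) -> float:
        return self.pi2 + self.pi12

    def overlap(self, M_eff: int | None = None) -> OverlapSummary:
        """Causal-count overlap summary against a template of M_eff variants.

        M_eff defaults to the fitting template size; for real data it is the
        reference-template size the counts should be reported against.
        """
        M = self.M if M_eff is None else M_eff
        n_a, n_b, n_sh = self.pi_a * M, self.pi_b * M, self.pi12 * M
        if n_a + n_b == 0:
            raise ZeroDivisionError("dice undefined: n_a + n_b = 0")
        rg = (self.rho_beta * self.pi12 / np.sqrt(self.pi_a * self.pi_b)
              if self.pi_a > 0 and self.pi_b > 0 else 0.0)
        return OverlapSummary(
            n_a, n_b, n_sh, 2.0 * n_sh / (n_a + n_b), rg,
            concordant_fraction(self.rho_beta),
        )

    def summary(self) -> str:
        ov = self.overlap()
        se = self.se or {}

        def _se(k):
            return f" (SE {se[k]:.3g})" if k in se else ""

        lines = [
            "Bivariate causal mixture fit",
            "-" * 46,
            f"pi1 (A-only)       {self.pi1:.3e}{_se('pi1')}",
            f"pi2 (B-only)       {self.pi2:.3e}{_se('pi2')}",
            f"pi12 (shared)      {self.pi12:.3e}{_se('pi12')}",
            f"rho_beta           {self.rho_beta:+.3f}{_se('rho_beta')}",
            f"rho0               {self.rho0:+.3f}{_se('rho0')}",
            f"log-likelihood     {self.loglik:.2f}",
            f"n_causal A/B/shared  {ov.n_a:.0f} / {ov.n_b:.0f} / {ov.n_shared:.0f}",
            f"Dice coefficient   {ov.dice:.3f}",
            f"genetic corr rg    {ov.rg:+.3f}",
            f"concordant shared  {100 * ov.concordant_fraction:.1f}%",
            f"converged          {self.converged}",
        ]
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "pi1": self.pi1, "pi2": self.pi2, "pi12": self.pi12,
            "rho_beta": self.rho_beta, "rho0": self.rho0,
            "loglik": self.loglik, "M": self.M,
            "converged": self.converged, "se": self.se,
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


class BivariateMixture:
    """Model object for the bivariate fit, conditional on two univariate fits.

    The per-trait polygenicities and variance parameters are held fixed at
    their univariate estimates; the free parameters are (pi12, rho_beta, rho0)
    with pi1 = pi_A - pi12 and pi2 = pi_B - pi12, so the constraint
    pi12 <= min(pi_A, pi_B) holds by construction.
    """

    def __init__(self, pair: PairedSumstats, ld: LDReference,
                 fit_a: UnivariateMixtureResults, fit_b: UnivariateMixtureResults,
                 config: MixtureConfig = MixtureConfig()):
        if not (fit_a.reliable and fit_b.reliable):
            warnings.warn("a univariate fit is flagged unreliable; bivariate "
                          "estimates inherit that caveat", stacklevel=2)
        self.config = config
        self.ld = ld
        self.fit_a = fit_a
        self.fit_b = fit_b
        rows = ld.rows_of(pair.table["SNP"].tolist())
        self.zA = pair.table["Z_A"].to_numpy(dtype=float)
        self.zB = pair.table["Z_B"].to_numpy(dtype=float)
        self.nA = pair.table["N_A"].to_numpy(dtype=float)
        self.nB = pair.table["N_B"].to_numpy(dtype=float)
        self.K, self.r2neigh = _neighbor_stats(ld, rows, config.r2_min)
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10,)))
        self.weights = ld.prune_weights(config.prune_r2, config.n_prune, rng)[rows]
        self._pi_max = min(fit_a.pi, fit_b.pi)
        # group variants by their (K, r2neigh, nA, nB) profile; Gaussian config
        # constants are shared within a slot.  Heterogeneous real data can
        # produce many profiles, so quantize r2neigh when the count explodes.
        prof = np.column_stack([self.K.astype(float), self.r2neigh, self.nA, self.nB])
        slots, kslot = np.unique(prof, axis=0, return_inverse=True)
        if slots.shape[0] > 4096:
            prof[:, 1] = np.round(prof[:, 1], 3)
            self.r2neigh = prof[:, 1].copy()
            slots, kslot = np.unique(prof, axis=0, return_inverse=True)
        self._slots = slots
        self._kslot = kslot.astype(np.int64).ravel()

    # -- objective ---------------------------------------------------------

    def _nll_at(self, pi12: float, rho_beta: float, rho0: float,
                mask: np.ndarray | None = None) -> float:
        a, b = self.fit_a, self.fit_b
        pi12 = float(np.clip(pi12, 0.0, self._pi_max))
        pi1 = max(a.pi - pi12, 0.0)
        pi2 = max(b.pi - pi12, 0.0)
        rho_beta = float(np.clip(rho_beta, -1 + 1e-9, 1 - 1e-9))
        rho0 = float(np.clip(rho0, -1 + 1e-9, 1 - 1e-9))
        tables = _biv_slot_tables(
            self._slots, pi1, pi2, pi12, a.sigma_b2, b.sigma_b2,
            a.sigma02, b.sigma02, rho_beta, rho0, self.config.m_max,
        )
        if mask is None:
            args = (self.zA, self.zB, self._kslot, self.weights)
        else:
            args = (self.zA[mask], self.zB[mask], self._kslot[mask],
                    self.weights[mask])
        return bivariate_nll_slots(*args, *tables)

    def _nll_theta(self, theta: np.ndarray, mask=None) -> float:
        pi12 = self._pi_max * float(expit(theta[0]))
        return self._nll_at(pi12, np.tanh(theta[1]), np.tanh(theta[2]), mask)

    def _optimize(self, theta0: np.ndarray, mask=None, maxfev: int | None = None):
        return minimize(
            self._nll_theta, theta0, args=(mask,), method="Nelder-Mead",
            options={"xatol": self.config.tol, "fatol": 1e-8,
                     "maxfev": maxfev or self.config.max_fev},
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, se_iterations: int | None = None) -> BivariateMixtureResults:
        """Fit (pi12, rho_beta, rho0); SEs from repeated subsampled refits.

        ``se_iterations`` overrides the config value; 0 skips SE estimation.
        """
        best, best_theta = np.inf, None
        for f in (0.05, 0.3, 0.7, 0.95):
            for rb in (-0.5, 0.0, 0.5):
                theta = np.array([logit(f), np.arctanh(rb), 0.0])
                v = self._nll_theta(theta)
                if v < best:
                    best, best_theta = v, theta
        res = self._optimize(best_theta)
        if not res.success:
            warnings.warn(f"bivariate fit did not converge: {res.message}", stacklevel=2)
        theta_hat = res.x
        pi12 = self._pi_max * float(expit(theta_hat[0]))

        n_se = self.config.se_iterations if se_iterations is None else se_iterations
        se = self._subsample_se(theta_hat, n_se) if n_se > 0 else None

        return BivariateMixtureResults(
            pi1=max(self.fit_a.pi - pi12, 0.0),
            pi2=max(self.fit_b.pi - pi12, 0.0),
            pi12=pi12,
            rho_beta=float(np.tanh(theta_hat[1])),
            rho0=float(np.tanh(theta_hat[2])),
            loglik=-float(res.fun),
            M=self.ld.n_variants,
            converged=bool(res.success),
            se=se,
            fit_a=self.fit_a,
            fit_b=self.fit_b,
        )

    def _subsample_se(self, theta_hat: np.ndarray, n_iter: int) -> dict:
        """SD of parameters over refits on random variant subsamples."""
        rng = np.random.default_rng(
            np.random.SeedSequence(self.config.seed, spawn_key=(11,))
        )
        M = self.zA.shape[0]
        m = max(int(round(self.config.se_subsample * M)), 50)
        draws = {"pi1": [], "pi2": [], "pi12": [], "rho_beta": [], "rho0": []}
        for _ in range(n_iter):
            mask = np.zeros(M, dtype=bool)
            mask[rng.choice(M, size=m, replace=False)] = True
            r = self._optimize(theta_hat.copy(), mask=mask, maxfev=150)
            pi12 = self._pi_max * float(expit(r.x[0]))
            draws["pi12"].append(pi12)
            draws["pi1"].append(max(self.fit_a.pi - pi12, 0.0))
            draws["pi2"].append(max(self.fit_b.pi - pi12, 0.0))
            draws["rho_beta"].append(float(np.tanh(r.x[1])))
            draws["rho0"].append(float(np.tanh(r.x[2])))
        return {k: float(np.std(v, ddof=1)) for k, v in draws.items()}


@dataclass
class MixtureDiagnostics:
    """Model-fit diagnostics against two degenerate reference models.

    The best fit is compared with (i) maximal overlap, pi12 = min(pi_A, pi_B),
    and (ii) independence-expected overlap, pi12 = pi_A * pi_B.  ``reliable``
    requires the best fit to beat both references by ``margin`` log-likelihood
    units AND both traits to clear the polygenicity floor — very low-polygenic
    traits are the known failure mode of this model family.
    """

    loglik_best: float
    loglik_max_overlap: float
    loglik_independent: float
    aic_best: float
    aic_max_overlap: float
    aic_independent: float
    max_overlap_rejected: bool
    independence_rejected: bool
    polygenicity_ok: bool
    reliable: bool


def model_fit_diagnostics(
    model: BivariateMixture,
    results: BivariateMixtureResults,
    margin: float = 2.0,
    pi_floor: float = 1e-3,
) -> MixtureDiagnostics:
    """Compare the fitted model with maximal-overlap and independence references."""
    a, b = model.fit_a, model.fit_b
    ll_best = results.loglik

    def _constrained(pi12_fixed: float) -> float:
        def nll(theta2):
            return model._nll_at(pi12_fixed, np.tanh(theta2[0]), np.tanh(theta2[1]))
        start = np.array([np.arctanh(np.clip(results.rho_beta, -0.95, 0.95)),
                          np.arctanh(np.clip(results.rho0, -0.95, 0.95))])
        r = minimize(nll, start, method="Nelder-Mead",
                     options={"xatol": model.config.tol, "maxfev": 300})
        return -float(r.fun)

    ll_max = _constrained(min(a.pi, b.pi))
    ll_ind = _constrained(min(a.pi * b.pi, min(a.pi, b.pi)))

    aic = lambda ll, k: 2.0 * k - 2.0 * ll
    polygenicity_ok = min(a.pi, b.pi) >= pi_floor
    max_rej = ll_best - ll_max > margin
    ind_rej = ll_best - ll_ind > margin
    return MixtureDiagnostics(
        loglik_best=ll_best,
        loglik_max_overlap=ll_max,
        loglik_independent=ll_ind,
        aic_best=aic(ll_best, 3),
        aic_max_overlap=aic(ll_max, 2),
        aic_independent=aic(ll_ind, 2),
        max_overlap_rejected=max_rej,
        independence_rejected=ind_rej,
        polygenicity_ok=polygenicity_ok,
        reliable=bool(max_rej and ind_rej and polygenicity_ok),
    )
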