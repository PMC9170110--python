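"""Numba kernels for the mixture likelihoods and LD pruning.

The kernels work on flat arrays (block-concatenated) so the Python layer can
stay vectorised.  All are deterministic given their inputs; randomness (pruning
orders, subsampling) is drawn outside and passed in.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True, fastmath=True)
def greedy_prune_block(r2: np.ndarray, order: np.ndarray, keep: np.ndarray) -> None:
    """Greedy maximal independent set at an r^2 threshold, in the given order.

    ``r2`` is the within-block squared-correlation matrix with the threshold
    already applied as a boolean (True = linked).  ``keep`` (bool, len block)
    is written in place.
    """
    n = order.shape[0]
    for ii in range(n):
        i = order[ii]
        ok = True
        for jj in range(ii):
            j = order[jj]
            if keep[j] and r2[i, j]:
                ok = False
                break
        keep[i] = ok


@njit(cache=True, fastmath=True)
def univariate_loglik_pervariant(
    z, nvec, K, r2neigh, pi, sigma_b2, sigma02, m_max, logfact, out
):
    """Per-variant log-likelihood of the point-normal causal mixture.

    The variant's own causal status (probability pi, full weight r^2 = 1) is
    treated exactly; its K[j]-1 LD neighbours enter through a binomial count
    m ~ Binom(K_j - 1, pi) with the mean neighbour weight r2neigh[j]:

      var(z | s, m) = (s + m * r2neigh_j) * n_j * sigma_b2 + sigma02,

    s in {0, 1} the self indicator.  Weights truncated at m_max are
    renormalised.
    """
    M = z.shape[0]
    # caller clamps pi into the open interval (0, 1)
    lpi = np.log(pi)
    l1mpi = np.log(1.0 - pi)
    for j in range(M):
        kn = K[j] - 1
        wsum = 0.0
        lik = 0.0
        base = nvec[j] * sigma_b2
        baseN = base * r2neigh[j]
        for m in range(min(kn, m_max) + 1):
            lwm = (
                logfact[kn] - logfact[m] - logfact[kn - m]
                + m * lpi + (kn - m) * l1mpi
            )
            if m > 0 and lwm < -36.8:
                break
            for s in range(2):
                if s + m > m_max:  # m_max caps the total causal count
                    continue
                lw = lwm + (lpi if s == 1 else l1mpi)
                w = np.exp(lw)
                var = s * base + m * baseN + sigma02
                w_pdf = w * np.exp(-0.5 * (LOG2PI + np.log(var) + z[j] * z[j] / var))
                wsum += w
                lik += w_pdf
        out[j] = np.log(lik / wsum) if lik > 0.0 else -745.0


@njit(cache=True, fastmath=True)
def univariate_nll(z, nvec, K, r2bar, w, pi, sigma_b2, sigma02, m_max, logfact):
    """Pruning-weighted negative log-likelihood for the univariate mixture."""
    M = z.shape[0]
    out = np.empty(M)
    univariate_loglik_pervariant(z, nvec, K, r2bar, pi, sigma_b2, sigma02, m_max, logfact, out)
    nll = 0.0
    for j in range(M):
        nll -= w[j] * out[j]
    return nll


@njit(cache=True, fastmath=True)
def bivariate_loglik_pervariant(
    zA, zB, nA, nB, K, r2neigh,
    pi1, pi2, pi12,
    sbA2, sbB2, s0A2, s0B2,
    rho_beta, rho0, m_max, logfact, out,
):
    """Per-variant log-likelihood of the four-component bivariate causal mixture.

    The variant's own component c0 (null / A-only / B-only / shared, with the
    mixture probabilities) is treated exactly at full weight r^2 = 1; its
    K_j - 1 LD neighbours enter through causal counts
    (m1, m2, m12) ~ Multinomial(K_j - 1; pi1, pi2, pi12), truncated at
    m1+m2+m12 <= m_max (weights renormalised), each at the mean neighbour
    weight r2neigh_j.  Conditional on (c0, counts), (zA, zB) is bivariate
    normal with
      VarA = (sA + (m1+m12)*r2neigh)*nA*sbA2 + s0A2
      VarB = (sB + (m2+m12)*r2neigh)*nB*sbB2 + s0B2
      Cov  = (s12 + m12*r2neigh)*sqrt(nA*nB*sbA2*sbB2)*rho_beta
             + rho0*sqrt(s0A2*s0B2)
    where sA = 1 if c0 is A-only or shared (sB analogous) and s12 = 1 if c0
    is shared.
    """
    M = zA.shape[0]
    pi0 = 1.0 - pi1 - pi2 - pi12
    if pi0 < 0.0:
        pi0 = 0.0
    lp = np.empty(4)
    lp[0] = np.log(pi0) if pi0 > 0.0 else -np.inf
    lp[1] = np.log(pi1) if pi1 > 0.0 else -np.inf
    lp[2] = np.log(pi2) if pi2 > 0.0 else -np.inf
    lp[3] = np.log(pi12) if pi12 > 0.0 else -np.inf
    cross_b = np.sqrt(sbA2 * sbB2) * rho_beta
    cov0 = rho0 * np.sqrt(s0A2 * s0B2)
    pic = pi1 + pi2 + pi12
    l_pic = np.log(pic) if pic > 0.0 else -np.inf
    l_1mpic = np.log(1.0 - pic) if pic < 1.0 else -np.inf
    for j in range(M):
        kn = K[j] - 1
        mm = kn if kn < m_max else m_max
        fullA = nA[j] * sbA2
        fullB = nB[j] * sbB2
        fullC = np.sqrt(nA[j] * nB[j]) * cross_b
        baseA = fullA * r2neigh[j]
        baseB = fullB * r2neigh[j]
        baseC = fullC * r2neigh[j]
        wsum = 0.0
        lik = 0.0
        za, zb = zA[j], zB[j]
        # enumerate neighbour configs by total causal count; once the binomial
        # level weight Binom(mtot; kn, pi_c) drops below 1e-16 the remaining
        # levels are numerically irrelevant (wsum is order 1)
        for mtot in range(mm + 1):
            if mtot > 0:
                if pic == 0.0:
                    break
                lvl = (
                    logfact[kn] - logfact[mtot] - logfact[kn - mtot]
                    + mtot * l_pic + (kn - mtot) * l_1mpic
                )
                if lvl < -36.8:
                    break
            m0 = kn - mtot
            if m0 > 0 and pi0 == 0.0:
                continue
            for m1 in range(mtot + 1):
                if m1 > 0 and pi1 == 0.0:
                    break
                for m2 in range(mtot - m1 + 1):
                    if m2 > 0 and pi2 == 0.0:
                        break
                    m12 = mtot - m1 - m2
                    if m12 > 0 and pi12 == 0.0:
                        continue
                    lwn = (
                        logfact[kn] - logfact[m1] - logfact[m2]
                        - logfact[m12] - logfact[m0]
                    )
                    if m1 > 0:
                        lwn += m1 * lp[1]
                    if m2 > 0:
                        lwn += m2 * lp[2]
                    if m12 > 0:
                        lwn += m12 * lp[3]
                    if m0 > 0:
                        lwn += m0 * lp[0]
                    for c0 in range(4):
                        if lp[c0] == -np.inf:
                            continue
                        if c0 > 0 and mtot + 1 > m_max:  # total causal cap
                            continue
                        sA = 1.0 if (c0 == 1 or c0 == 3) else 0.0
                        sB = 1.0 if (c0 == 2 or c0 == 3) else 0.0
                        s12 = 1.0 if c0 == 3 else 0.0
                        w = np.exp(lwn + lp[c0])
                        varA = sA * fullA + (m1 + m12) * baseA + s0A2
                        varB = sB * fullB + (m2 + m12) * baseB + s0B2
                        cov = s12 * fullC + m12 * baseC + cov0
                        det = varA * varB - cov * cov
                        if det < 1e-300:
                            continue
                        quad = (
                            varB * za * za - 2.0 * cov * za * zb + varA * zb * zb
                        ) / det
                        w_pdf = w * np.exp(-0.5 * (2.0 * LOG2PI + np.log(det) + quad))
                        wsum += w
                        lik += w_pdf
        out[j] = np.log(lik / wsum) if lik > 0.0 and wsum > 0.0 else -745.0


@njit(cache=True, fastmath=True)
def bivariate_nll_slots(zA, zB, kslot, wj, Wc, Ac, Bc, Cc, offsets, inv_wsum):
    """Weighted negative log-likelihood from per-slot precomputed config tables.

    Variants sharing a (K, r2bar, nA, nB) profile share all config constants:
    for config c, Wc = weight / (2*pi*sqrt(det)), (Ac, Bc) = -varB/(2 det) and
    -varA/(2 det), Cc = cov/det, so the per-variant term is
    sum_c Wc * exp(Ac*zA^2 + Bc*zB^2 + Cc*zA*zB), renormalised by the slot's
    truncated weight total.
    """
    M = zA.shape[0]
    nll = 0.0
    for j in range(M):
        s = kslot[j]
        za, zb = zA[j], zB[j]
        za2 = za * za
        zb2 = zb * zb
        zab = za * zb
        lik = 0.0
        for c in range(offsets[s], offsets[s + 1]):
            lik += Wc[c] * np.exp(Ac[c] * za2 + Bc[c] * zb2 + Cc[c] * zab)
        if lik > 0.0:
            nll -= wj[j] * np.log(lik * inv_wsum[s])
        else:
            nll += wj[j] * 745.0
    return nll


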