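"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written as plain double loops over small inputs, sharing no
code with the package's implementations.
"""

from fractions import Fraction
from math import comb

import numpy as np


def greedy_clump_oracle(table, r2_lookup, threshold):
    """Greedy clumping by (FDR, P, BP, SNP) order; plain quadratic loop."""
    order = sorted(table, key=lambda r: (r["FDR"], r["P"], r["BP"], r["SNP"]))
    kept = []
    for row in order:
        if all(r2_lookup(row["SNP"], k["SNP"]) < threshold for k in kept):
            kept.append(row)
    return [r["SNP"] for r in kept]


def define_loci_oracle(leads, independent, all_rows, r2_lookup,
                       merge_distance=250_000, candidate_fdr=0.1, candidate_r2=0.6):
    """Exhaustive locus construction: assignment, candidates, interval merge."""
    info = {r["SNP"]: r for r in all_rows}
    lead_of = {}
    for s in independent:
        best, best_r2 = None, -1.0
        for l in leads:
            r2 = 1.0 if l == s else r2_lookup(s, l)
            if r2 > best_r2:
                best, best_r2 = l, r2
        lead_of[s] = best

    blocks = []
    for l in leads:
        cands = set()
        for s in independent:
            if lead_of[s] != l:
                continue
            cands.add(s)
            for r in all_rows:
                if r["FDR"] < candidate_fdr and r2_lookup(s, r["SNP"]) >= candidate_r2:
                    cands.add(r["SNP"])
        bps = [info[c]["BP"] for c in cands]
        blocks.append({
            "chrom": info[l]["CHR"], "min": min(bps), "max": max(bps),
            "lead": l, "lead_fdr": info[l]["FDR"],
            "inds": {s for s in independent if lead_of[s] == l},
            "cands": cands,
        })

    # merge any same-chromosome pair with gap < merge_distance, to fixed point
    changed = True
    while changed:
        changed = False
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                a, b = blocks[i], blocks[j]
                if a["chrom"] != b["chrom"]:
                    continue
                gap = max(a["min"], b["min"]) - min(a["max"], b["max"])
                if gap < merge_distance:
                    lead = a if a["lead_fdr"] <= b["lead_fdr"] else b
                    merged = {
                        "chrom": a["chrom"],
                        "min": min(a["min"], b["min"]),
                        "max": max(a["max"], b["max"]),
                        "lead": lead["lead"], "lead_fdr": lead["lead_fdr"],
                        "inds": a["inds"] | b["inds"],
                        "cands": a["cands"] | b["cands"],
                    }
                    blocks = [blocks[k] for k in range(len(blocks)) if k not in (i, j)]
                    blocks.append(merged)
                    changed = True
                    break
            if changed:
                break
    return sorted(blocks, key=lambda b: (b["chrom"], b["min"]))


def binom_tail_oracle(n, k):
    """Exact one-sided upper-tail binomial probability at p = 1/2 (rational)."""
    return Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2 ** n)


def random_locus_toy(seed, n_variants=30):
    """Randomized small locus-definition problem with a PSD factor-model LD."""
    rng = np.random.default_rng(seed)
    n_chrom = rng.integers(1, 4)
    chroms = np.sort(rng.integers(1, n_chrom + 1, size=n_variants))
    bp = np.empty(n_variants, dtype=int)
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        bp[idx] = np.sort(rng.choice(np.arange(1, 2000) * 1_000, size=idx.size,
                                     replace=False))
    # PSD correlation per chromosome from random factor loadings
    blocks = []
    block_index = np.empty(n_variants, dtype=np.int64)
    for b, c in enumerate(np.unique(chroms)):
        idx = np.flatnonzero(chroms == c)
        load = rng.normal(size=(idx.size, 2))
        cov = load @ load.T + np.diag(rng.uniform(0.05, 1.0, idx.size))
        d = np.sqrt(np.diag(cov))
        blocks.append(cov / np.outer(d, d))
        block_index[idx] = b
    fdr = rng.uniform(0, 0.2, size=n_variants)
    p = fdr * rng.uniform(0.1, 1.0, size=n_variants)
    snps = [f"v{i:02d}" for i in range(n_variants)]
    return snps, chroms, bp, blocks, block_index, fdr, p
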