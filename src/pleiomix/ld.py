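"""Block-structured LD reference and LD-aware helpers (pruning, partner stats).

The reference is block diagonal: signed correlations within blocks, zero
across blocks.  Synthetic references use AR(1) decay, ``r(i,j) = decay^|i-j|``,
which is positive semi-definite by construction and gives realistic clumping
structure at negligible cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import greedy_prune_block

__all__ = ["LDReference", "build_ld_reference"]


@dataclass
class LDReference:
    """Pairwise LD (signed r) over an ordered variant template.

    Attributes
    ----------
    template : pandas.DataFrame
        Columns ``SNP CHR BP``, one row per template variant, sorted by (CHR, BP).
    blocks : list of numpy.ndarray
        Per-block signed correlation matrices (symmetric, unit diagonal, PSD).
    block_index : numpy.ndarray of int
        Block id per template variant.
    """

    template: pd.DataFrame
    blocks: list
    block_index: np.ndarray
    _offsets: np.ndarray = field(init=False, repr=False)
    _pos_in_block: np.ndarray = field(init=False, repr=False)
    _key_to_row: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        sizes = np.array([b.shape[0] for b in self.blocks])
        self._offsets = np.concatenate([[0], np.cumsum(sizes)])
        pos = np.empty(len(self.template), dtype=np.int64)
        for bid in range(len(self.blocks)):
            idx = np.flatnonzero(self.block_index == bid)
            pos[idx] = np.arange(idx.size)
        self._pos_in_block = pos
        self._key_to_row = {k: i for i, k in enumerate(self.template["SNP"])}

    @property
    def n_variants(self) -> int:
        return len(self.template)

    def row_of(self, key: str) -> int:
        """Template row index of a variant key; KeyError if absent."""
        return self._key_to_row[key]

    def rows_of(self, keys) -> np.ndarray:
        return np.fromiter((self._key_to_row[k] for k in keys), dtype=np.int64,
                           count=len(keys))

    def r(self, i: int, j: int) -> float:
        """Signed correlation between template rows i and j (0 across blocks)."""
        bi, bj = self.block_index[i], self.block_index[j]
        if bi != bj:
            return 0.0
        return float(self.blocks[bi][self._pos_in_block[i], self._pos_in_block[j]])

    def r2(self, i: int, j: int) -> float:
        return self.r(i, j) ** 2

    def partner_stats(self, r2_min: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant LD-partner count and mean partner r^2.

        A partner is any variant (self included) with r^2 >= ``r2_min``.
        Returns ``(K, r2bar)``: partner counts (int64) and the mean of the
        partners' r^2 values — the two LD moments the mixture likelihood uses.
        """
        K = np.empty(self.n_variants, dtype=np.int64)
        r2bar = np.empty(self.n_variants)
        for bid, block in enumerate(self.blocks):
            idx = np.flatnonzero(self.block_index == bid)
            r2m = block**2
            mask = r2m >= r2_min
            k = mask.sum(axis=1)
            s = np.where(mask, r2m, 0.0).sum(axis=1)
            K[idx] = k
            r2bar[idx] = s / np.maximum(k, 1)
        return K, r2bar

    def random_prune(self, r2_threshold: float, rng: np.random.Generator) -> np.ndarray:
        """One random-pruning pass: boolean keep mask over the template.

        Variants are visited in random order within each block; a variant is
        kept iff its r^2 with every previously kept variant is below the
        threshold (so each LD clique contributes one random representative).
        """
        keep = np.zeros(self.n_variants, dtype=bool)
        for bid, block in enumerate(self.blocks):
            idx = np.flatnonzero(self.block_index == bid)
            linked = (block**2) >= r2_threshold
            np.fill_diagonal(linked, False)
            order = rng.permutation(idx.size)
            kb = np.zeros(idx.size, dtype=bool)
            greedy_prune_block(linked, order, kb)
            keep[idx] = kb
        return keep

    def prune_weights(
        self, r2_threshold: float = 0.8, n_iter: int = 20,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Inclusion frequency over repeated random pruning passes.

        Used as per-variant weights in the mixture likelihood so that dense LD
        regions do not dominate the fit.
        """
        rng = rng if rng is not None else np.random.default_rng(0)
        w = np.zeros(self.n_variants)
        for _ in range(n_iter):
            w += self.random_prune(r2_threshold, rng)
        return w / n_iter

    def r2_submatrix(self, rows: np.ndarray) -> np.ndarray:
        """Dense r^2 matrix for an arbitrary subset of template rows."""
        m = rows.size
        out = np.zeros((m, m))
        bids = self.block_index[rows]
        pos = self._pos_in_block[rows]
        for bid in np.unique(bids):
            sel = np.flatnonzero(bids == bid)
            sub = self.blocks[bid][np.ix_(pos[sel], pos[sel])] ** 2
            out[np.ix_(sel, sel)] = sub
        return out


def build_ld_reference(
    n_blocks: int, block_size: int, decay: float, seed: int = 0
) -> LDReference:
    """Build a synthetic block-diagonal AR(1) LD reference.

    Within a block ``r(i, j) = decay ** |i - j|``; cross-block r is zero.
    Variants are spaced 10 kb apart within a block, blocks are separated by
    1 Mb gaps and distributed contiguously over chromosomes 1–22.  ``decay=0``
    gives identity blocks (no LD).

    The construction is deterministic; ``seed`` is accepted for interface
    stability and unused.
    """
    if n_blocks < 1 or block_size < 1:
        raise ValueError("n_blocks and block_size must be >= 1")
    if not (0.0 <= decay < 1.0):
        raise ValueError(f"decay must be in [0, 1), got {decay}")

    d = np.arange(block_size)
    block = decay ** np.abs(d[:, None] - d[None, :])
    blocks = [block.copy() for _ in range(n_blocks)]

    per_chrom = -(-n_blocks // 22)  # ceil
    snp, chrom, bp, bidx = [], [], [], []
    counter = 0
    for b in range(n_blocks):
        c = b // per_chrom + 1
        b_on_c = b % per_chrom
        start = 1_000_000 + b_on_c * (block_size * 10_000 + 1_000_000)
        for i in range(block_size):
            counter += 1
            snp.append(f"snp{counter:07d}")
            chrom.append(c)
            bp.append(start + i * 10_000)
            bidx.append(b)
    template = pd.DataFrame({"SNP": snp, "CHR": chrom, "BP": bp})
    return LDReference(template, blocks, np.asarray(bidx, dtype=np.int64))
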