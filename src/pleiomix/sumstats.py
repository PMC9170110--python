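"""Reading, validation, harmonization and filtering of GWAS summary statistics.

All genomic coordinates in this package are 1-based inclusive (BED input is
converted on read).  The canonical in-memory container for one trait is a
pandas DataFrame with columns ``SNP CHR BP A1 A2 Z P N``; a harmonized
two-trait table is a :class:`PairedSumstats`.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SumstatsFormatError",
    "GenomicInterval",
    "PairedSumstats",
    "HarmonizationReport",
    "DEFAULT_EXCLUSION_REGIONS",
    "read_sumstats",
    "write_sumstats",
    "harmonize_pair",
    "read_bed",
    "apply_exclusion_regions",
]

#: Minimum positive p-value; underflowed zeros in real GWAS files are clamped here.
P_FLOOR = float(np.finfo(np.float64).tiny)

#: Canonical column order of the on-disk tab-delimited format.
COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "P", "N"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


class SumstatsFormatError(ValueError):
    """Raised for malformed summary-statistics input (fail-fast, no silent drops)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: int
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval {self.label!r}: start {self.start} > end {self.end}"
            )

    def contains(self, chrom: int, bp: int) -> bool:
        return chrom == self.chrom and self.start <= bp <= self.end

    def overlaps(self, chrom: int, start: int, end: int) -> bool:
        """True if [start, end] on ``chrom`` shares at least one base with this interval."""
        return chrom == self.chrom and start <= self.end and end >= self.start


#: Long-range high-LD regions excluded before cross-trait FDR analyses:
#: the extended MHC and the 8p23.1 inversion region.  The 8p23.1 span is the
#: cytoband extent on GRCh37 and is configurable (no canonical coordinates exist).
DEFAULT_EXCLUSION_REGIONS = (
    GenomicInterval(6, 25_119_106, 33_854_733, "MHC"),
    GenomicInterval(8, 7_200_000, 12_500_000, "8p23.1"),
)


@dataclass
class HarmonizationReport:
    """Bookkeeping from allele harmonization of two traits."""

    n_shared_keys: int = 0
    n_flipped: int = 0
    n_ambiguous: int = 0
    n_irreconcilable: int = 0
    n_excluded_region: int = 0


@dataclass
class PairedSumstats:
    """Two harmonized GWAS aligned on shared variants.

    ``table`` has columns ``SNP CHR BP A1 A2 Z_A Z_B P_A P_B N_A N_B`` with
    alleles coded on trait A's effect allele (Z_B sign-flipped where trait B's
    coding differed).  Rows are sorted by (CHR, BP).
    """

    table: pd.DataFrame
    report: HarmonizationReport = field(default_factory=HarmonizationReport)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variants(self) -> pd.Series:
        return self.table["SNP"]

    def __getattr__(self, name):
        # convenience accessors: z_a, p_b, n_a ... as numpy arrays
        key = name.upper()
        if key in ("Z_A", "Z_B", "P_A", "P_B", "N_A", "N_B", "CHR", "BP"):
            return self.table[key].to_numpy()
        raise AttributeError(name)

    def swapped(self) -> "PairedSumstats":
        """Return the pair with trait labels A and B exchanged."""
        t = self.table.rename(
            columns={"Z_A": "Z_B", "Z_B": "Z_A", "P_A": "P_B", "P_B": "P_A",
                     "N_A": "N_B", "N_B": "N_A"}
        )[self.table.columns]
        return PairedSumstats(t, self.report)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _z_from_p_sign(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    # two-sided p back to signed z: |z| = Phi^-1(1 - p/2)
    return sign * sps.norm.isf(np.clip(p, P_FLOOR, 1.0) / 2.0)


def read_sumstats(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited GWAS summary-statistics file into the canonical frame.

    Parameters
    ----------
    path : str or Path
        Tab-delimited file with a header; transparently gzip-decompressed when the
        name ends in ``.gz``.
    column_map : dict, optional
        Mapping of logical names (``snp, chr, bp, a1, a2, z, p, n, beta, se``)
        to the actual header names in the file.  Defaults to the canonical
        header ``SNP CHR BP A1 A2 Z P N``.

    The z-score is taken from the ``z`` column when present, else derived as
    ``beta/se``, else from the two-sided p-value plus the sign of ``beta``.
    Missing p-values are filled from z via ``p = 2*Phi(-|z|)``; supplied
    (z, p) pairs are checked for consistency at 1e-6 relative tolerance.
    Rows come back sorted by (CHR, BP); p=0 is clamped to the smallest
    positive double.

    Raises
    ------
    SumstatsFormatError
        If a mandatory column is absent (named in the message) or a row fails
        validation (reported with its 1-based data line number).
    """
    defaults = {
        "snp": "SNP", "chr": "CHR", "bp": "BP", "a1": "A1", "a2": "A2",
        "z": "Z", "p": "P", "n": "N", "beta": "BETA", "se": "SE",
    }
    cmap = dict(defaults)
    if column_map:
        cmap.update({k.lower(): v for k, v in column_map.items()})

    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    have = set(df.columns)

    for logical in ("snp", "chr", "bp", "a1", "a2", "n"):
        if cmap[logical] not in have:
            raise SumstatsFormatError(f"missing mandatory column {cmap[logical]!r}")
    has_z = cmap["z"] in have
    has_p = cmap["p"] in have
    has_beta = cmap["beta"] in have and cmap["se"] in have
    has_p_sign = cmap["p"] in have and cmap["beta"] in have
    if not (has_z or has_beta or has_p_sign):
        raise SumstatsFormatError(
            f"need column {cmap['z']!r}, or {cmap['beta']!r}+{cmap['se']!r}, "
            f"or {cmap['p']!r}+{cmap['beta']!r} (effect sign)"
        )

    def _col(logical, kind, required=True):
        name = cmap[logical]
        if name not in have:
            return None
        raw = df[name]
        try:
            if kind is int:
                vals = pd.to_numeric(raw, errors="raise").astype(np.int64)
            else:
                vals = pd.to_numeric(raw, errors="raise").astype(np.float64)
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw, errors="coerce")
            line = int(np.flatnonzero(bad.isna() & raw.notna())[0]) + 1
            raise SumstatsFormatError(
                f"column {name!r}: unparseable value at data line {line}"
            ) from None
        if required and vals.isna().any():
            line = int(np.flatnonzero(vals.isna())[0]) + 1
            raise SumstatsFormatError(f"column {name!r}: missing value at data line {line}")
        return vals.to_numpy()

    out = pd.DataFrame(
        {
            "SNP": df[cmap["snp"]].astype(str),
            "CHR": _col("chr", int),
            "BP": _col("bp", int),
            "A1": df[cmap["a1"]].astype(str).str.upper(),
            "A2": df[cmap["a2"]].astype(str).str.upper(),
        }
    )

    z = _col("z", float) if has_z else None
    p = _col("p", float) if has_p else None
    if z is None:
        if has_beta:
            beta, se = _col("beta", float), _col("se", float)
            z = beta / se
        else:
            beta = _col("beta", float)
            z = _z_from_p_sign(p, np.sign(beta))
    if p is None:
        p = 2.0 * sps.norm.sf(np.abs(z))
    else:
        p = np.clip(p, P_FLOOR, None)
        if has_z:
            expected = 2.0 * sps.norm.sf(np.abs(z))
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(p - expected) / np.maximum(expected, P_FLOOR)
            bad = np.flatnonzero((rel > 1e-6) & (expected > 1e-300))
            if bad.size:
                raise SumstatsFormatError(
                    f"z/p inconsistent at data line {bad[0] + 1}: "
                    f"p={p[bad[0]]:.6g}, 2*Phi(-|z|)={expected[bad[0]]:.6g}"
                )
    out["Z"] = z
    out["P"] = np.clip(p, P_FLOOR, 1.0)
    out["N"] = _col("n", int)

    _validate(out)
    out = out.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    return out


def _validate(df: pd.DataFrame) -> None:
    for i, (a1, a2) in enumerate(zip(df["A1"], df["A2"])):
        if a1 not in _VALID_ALLELES or a2 not in _VALID_ALLELES:
            raise SumstatsFormatError(f"invalid allele at data line {i + 1}: {a1}/{a2}")
        if a1 == a2:
            raise SumstatsFormatError(f"a1 == a2 at data line {i + 1}")
    if (df["P"] <= 0).any() or (df["P"] > 1).any():
        line = int(np.flatnonzero((df["P"] <= 0) | (df["P"] > 1))[0]) + 1
        raise SumstatsFormatError(f"p outside (0,1] at data line {line}")
    if (df["N"] <= 0).any():
        line = int(np.flatnonzero(df["N"] <= 0)[0]) + 1
        raise SumstatsFormatError(f"non-positive N at data line {line}")
    dup = df.duplicated(subset=["CHR", "BP", "A1", "A2"])
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 1
        raise SumstatsFormatError(f"duplicate (CHR,BP,A1,A2) at data line {line}")


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write the canonical frame as tab-delimited text (gzip if path ends in .gz).

    Reals are written with 17 significant digits so a read_sumstats round trip
    reproduces them to better than 1e-12.
    """
    out = df[COLUMNS].copy()
    with _open_text_w(path) as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write(
                f"{row.SNP}\t{row.CHR}\t{row.BP}\t{row.A1}\t{row.A2}\t"
                f"{row.Z:.17g}\t{row.P:.17g}\t{row.N}\n"
            )


def _open_text_w(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize_pair(a: pd.DataFrame, b: pd.DataFrame) -> PairedSumstats:
    """Align two sumstats tables on shared variant ids with consistent allele coding.

    Trait B rows whose alleles are swapped relative to trait A (directly or on the
    opposite strand) have Z_B negated.  Strand-ambiguous (A/T, C/G) variants are
    dropped and counted, as are variants whose allele pairs cannot be reconciled.
    The operation is idempotent: harmonizing an already harmonized pair is a no-op.
    """
    bi = b.set_index("SNP")
    keys = a["SNP"][a["SNP"].isin(bi.index)]
    rep = HarmonizationReport(n_shared_keys=len(keys))

    rows = []
    ai = a.set_index("SNP")
    for key in keys:
        ra, rb = ai.loc[key], bi.loc[key]
        a1, a2 = ra["A1"], ra["A2"]
        b1, b2 = rb["A1"], rb["A2"]
        if _is_palindromic(a1, a2) or _is_palindromic(b1, b2):
            rep.n_ambiguous += 1
            continue
        if (b1, b2) == (a1, a2):
            flip = False
        elif (b1, b2) == (a2, a1):
            flip = True
        elif (_COMPLEMENT[b1], _COMPLEMENT[b2]) == (a1, a2):
            flip = False
        elif (_COMPLEMENT[b1], _COMPLEMENT[b2]) == (a2, a1):
            flip = True
        else:
            rep.n_irreconcilable += 1
            continue
        if flip:
            rep.n_flipped += 1
        rows.append(
            (key, int(ra["CHR"]), int(ra["BP"]), a1, a2,
             float(ra["Z"]), -float(rb["Z"]) if flip else float(rb["Z"]),
             float(ra["P"]), float(rb["P"]), int(ra["N"]), int(rb["N"]))
        )
    table = pd.DataFrame(
        rows,
        columns=["SNP", "CHR", "BP", "A1", "A2", "Z_A", "Z_B", "P_A", "P_B", "N_A", "N_B"],
    )
    table = table.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    return PairedSumstats(table, rep)


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    intervals = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom = int(parts[0].removeprefix("chr"))
            start, end = int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            intervals.append(GenomicInterval(chrom, start + 1, end, label))
    return intervals


def apply_exclusion_regions(
    pair: PairedSumstats,
    regions=DEFAULT_EXCLUSION_REGIONS,
) -> PairedSumstats:
    """Drop variants inside any exclusion interval (1-based inclusive boundaries).

    Idempotent; the removed count is accumulated on the harmonization report.
    An empty region list is the identity.
    """
    if not regions:
        return pair
    chrom = pair.table["CHR"].to_numpy()
    bp = pair.table["BP"].to_numpy()
    drop = np.zeros(len(pair.table), dtype=bool)
    for iv in regions:
        drop |= (chrom == iv.chrom) & (bp >= iv.start) & (bp <= iv.end)
    n_removed = int(drop.sum())
    if n_removed == len(pair.table):
        warnings.warn("all variants fell inside exclusion regions", stacklevel=2)
    rep = replace(pair.report)
    rep.n_excluded_region = pair.report.n_excluded_region + n_removed
    return PairedSumstats(pair.table.loc[~drop].reset_index(drop=True), rep)
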