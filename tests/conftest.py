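"""Shared fixtures: small LD references and toy summary-statistics tables."""

import numpy as np
import pandas as pd
import pytest

from pleiomix import build_ld_reference


@pytest.fixture(scope="session")
def ld_no_ld():
    """600 variants in identity blocks (no LD)."""
    return build_ld_reference(60, 10, 0.0)


@pytest.fixture(scope="session")
def ld_ar():
    """600 variants, AR(1) decay 0.9 blocks of 10."""
    return build_ld_reference(60, 10, 0.9)


def make_sumstats(rows):
    """Build a canonical single-trait frame from (snp, chr, bp, a1, a2, z) rows."""
    from scipy.stats import norm

    df = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "Z"])
    df["P"] = 2.0 * norm.sf(np.abs(df["Z"]))
    df["N"] = 10_000
    return df
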