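"""Gene-family expansion tests across four species.

Per family, a Pearson chi-square test (df = 3) compares the observed
per-species member counts with counts proportional to each species'
genome-wide totals (the proportional-share null; an equal-shares null is
available behind a flag).  P-values are Bonferroni-adjusted across
families, and for families significant after adjustment the expanded
species is the one with the largest positive Pearson residual.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SPECIES = ("At", "Al", "Br", "Bo")


def family_chi2_test(
    table: pd.DataFrame,
    species_totals: dict | None = None,
    alpha: float = 0.05,
    equal_shares: bool = False,
) -> pd.DataFrame:
    """Chi-square expansion test per family with Bonferroni correction.

    ``table`` has a ``family_id`` column plus one count column per species.
    ``species_totals`` defaults to the column sums.  Families with zero
    total are skipped (logged); families with any expected cell < 1 are
    flagged ``low_expected`` (the chi-square approximation is unreliable
    there).
    """
    species = [s for s in SPECIES if s in table.columns]
    if len(species) < 2:
        raise ValueError("need counts for at least two species")
    counts = table[species].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative family counts")

    if equal_shares:
        shares = np.full(len(species), 1.0 / len(species))
    else:
        if species_totals is None:
            totals = counts.sum(axis=0)
        else:
            totals = np.array([species_totals[s] for s in species], dtype=float)
        if (totals < counts.sum(axis=0) - 1e-9).any():
            raise ValueError("species totals smaller than column sums")
        shares = totals / totals.sum()

    family_total = counts.sum(axis=1)
    nonzero = family_total > 0
    n_skipped = int((~nonzero).sum())
    if n_skipped:
        logger.info("skipping %d families with zero total count", n_skipped)

    expected = family_total[:, None] * shares[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (counts - expected) / np.sqrt(expected)
    chi2 = np.where(nonzero, np.nansum(resid**2, axis=1), np.nan)
    df = len(species) - 1
    p = np.where(nonzero, stats.chi2.sf(chi2, df), np.nan)
    n_tested = int(nonzero.sum())
    p_bonf = np.minimum(p * n_tested, 1.0)

    expanded = np.full(len(table), None, dtype=object)
    sig = nonzero & (p_bonf < alpha)
    if sig.any():
        arg = np.nanargmax(np.where(np.isnan(resid), -np.inf, resid)[sig], axis=1)
        expanded[sig] = np.array(species)[arg]

    out = table[["family_id"]].copy()
    out["chi2"] = chi2
    out["p"] = p
    out["p_bonferroni"] = p_bonf
    out["expanded_species"] = expanded
    out["low_expected"] = nonzero & (expected < 1.0).any(axis=1)
    out["tested"] = nonzero
    return out
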