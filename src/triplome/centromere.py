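"""Centromere mapping from half-tetrad heterozygosity gradients.

Progeny derived from first-division-restitution (FDR) unreduced gametes
inherit one chromatid from each parental homolog, so every locus at the
centromere is heterozygous and heterozygosity decays with map distance as
crossovers randomise which parental allele each chromatid carries.  The
centromere is therefore estimated as the maximum of a smoothed per-marker
heterozygosity profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def heterozygosity_profile(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-marker fraction of heterozygous progeny.

    ``genotypes``: marker, chrom, pos, then one column per progeny with
    states het/homA/homB or missing (NaN).  Missing states are excluded
    from denominators; all-missing markers yield NaN.
    """
    states = genotypes.iloc[:, 3:]
    n_obs = states.notna().sum(axis=1)
    n_het = (states == "het").sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0, n_het / n_obs.replace(0, 1), np.nan)
    out = genotypes[["marker", "chrom", "pos"]].copy()
    out["n_obs"] = n_obs.to_numpy()
    out["het_freq"] = freq
    return out


@dataclass
class CentromereEstimate:
    chrom: str
    pos_bp: float | None
    interval_bp: tuple | None
    max_het: float
    flat_flag: bool


def estimate_centromere(
    profile: pd.DataFrame,
    smoothing_window: int = 5,
    support_drop: float = 0.05,
    bp_space: bool = False,
) -> CentromereEstimate:
    """Smoothed-argmax centromere estimate for one chromosome.

    A moving average of width ``smoothing_window`` is taken over marker
    index (or, with ``bp_space=True``, over a uniform resampling of the
    profile in base-pair space); the point estimate is the position of the
    smoothed maximum, with tied runs resolved to their midpoint.  The
    support interval is the contiguous run around the maximum where the
    smoothed profile stays within ``support_drop`` of it.  Profiles whose
    total range is below ``support_drop`` are flagged flat and return no
    estimate.
    """
    prof = profile.dropna(subset=["het_freq"]).sort_values("pos")
    chrom = str(prof["chrom"].iloc[0]) if len(prof) else ""
    pos = prof["pos"].to_numpy(dtype=float)
    het = prof["het_freq"].to_numpy(dtype=float)
    if len(het) < smoothing_window:
        raise ValueError(
            f"need at least {smoothing_window} informative markers"
        )
    if bp_space:
        grid = np.linspace(pos[0], pos[-1], len(pos))
        het = np.interp(grid, pos, het)
        pos = grid
    kernel = np.ones(smoothing_window) / smoothing_window
    # reflect-pad so the smoothed series has the same length/alignment
    padded = np.concatenate([
        het[smoothing_window // 2:0:-1], het,
        het[-2:-(smoothing_window - smoothing_window // 2) - 1:-1],
    ])
    smooth = np.convolve(padded, kernel, mode="valid")[: len(het)]

    if smooth.max() - smooth.min() < support_drop:
        return CentromereEstimate(chrom, None, None, float(smooth.max()), True)

    mmax = smooth.max()
    tied = np.flatnonzero(np.isclose(smooth, mmax))
    # midpoint of the contiguous tied run containing the first maximum
    run = [tied[0]]
    for t in tied[1:]:
        if t == run[-1] + 1:
            run.append(t)
        else:
            break
    center = 0.5 * (pos[run[0]] + pos[run[-1]])

    ok = smooth >= mmax - support_drop
    lo = run[0]
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = run[-1]
    while hi < len(ok) - 1 and ok[hi + 1]:
        hi += 1
    return CentromereEstimate(
        chrom, float(center), (float(pos[lo]), float(pos[hi])),
        float(mmax), False,
    )


def estimate_all_centromeres(
    genotypes: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Per-chromosome estimates from a pooled genotype matrix."""
    prof = heterozygosity_profile(genotypes)
    rows = []
    for chrom, sub in prof.groupby("chrom"):
        est = estimate_centromere(sub, **kwargs)
        rows.append(
            (chrom, est.pos_bp,
             est.interval_bp[0] if est.interval_bp else None,
             est.interval_bp[1] if est.interval_bp else None,
             est.max_het, est.flat_flag)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "centromere_pos", "interval_lo", "interval_hi",
                 "max_het", "flat_flag"],
    )
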