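"""Genome-wide, per-feature, metagene and binned-track methylation summaries.

The primary "level" statistic is the site fraction: among cytosines tested at
``min_depth`` or more reads, the fraction called methylated.  A read-weighted
alternative (sum k / sum n) is available where noted.  Metagene profiles are
per-gene-then-mean aggregated so deeply covered genes do not dominate; the
pooled-site mode is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methcall import STATUS_METHYLATED, STATUS_UNTESTED

logger = logging.getLogger(__name__)


def context_levels(calls: pd.DataFrame, min_depth: int = 1) -> dict:
    """Percent methylated cytosines per context among tested sites.

    Contexts with no tested site map to NaN (undefined, not zero).
    """
    out = {}
    tested = (calls["status"] != STATUS_UNTESTED) & (
        calls["eff_CT_count"] >= min_depth
    )
    for ctx, grp in calls[tested].groupby("context"):
        out[ctx] = 100.0 * (grp["status"] == STATUS_METHYLATED).mean()
    for ctx in ("CG", "CHG", "CHH"):
        out.setdefault(ctx, float("nan"))
    return out


def _sites_by_chrom(calls: pd.DataFrame) -> dict:
    """Index tested/methylated flags by chromosome, position-sorted."""
    index = {}
    for chrom, grp in calls.groupby("chrom"):
        grp = grp.sort_values("pos")
        index[chrom] = (
            grp["pos"].to_numpy(),
            grp["context"].to_numpy(),
            (grp["status"] == STATUS_METHYLATED).to_numpy(),
            (grp["status"] != STATUS_UNTESTED).to_numpy(),
            grp["C_count"].to_numpy(),
            grp["eff_CT_count"].to_numpy(),
        )
    return index


def feature_levels(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    by: str = "part",
    weighted: bool = False,
) -> pd.DataFrame:
    """Methylation level per feature class (or gene category) and context.

    ``features`` has columns gene_id, chrom, strand, part, start, end,
    category; ``by`` selects the grouping column.  A site overlapped by
    several intervals of one class counts once for that class.  With
    ``weighted=True`` the level is read-weighted (sum k / sum n) instead of
    the site fraction.
    """
    if by not in ("part", "category"):
        raise ValueError("by must be 'part' or 'category'")
    index = _sites_by_chrom(calls)
    keys = features[by].unique()
    rows = []
    for key in keys:
        sub = features[features[by] == key]
        picked = {}  # chrom -> site index array
        for chrom, grp in sub.groupby("chrom"):
            if chrom not in index:
                continue
            pos = index[chrom][0]
            sel = []
            for s, e in zip(grp["start"], grp["end"]):
                lo = np.searchsorted(pos, s, side="left")
                hi = np.searchsorted(pos, e, side="right")
                if hi > lo:
                    sel.append(np.arange(lo, hi))
            if sel:
                picked[chrom] = np.unique(np.concatenate(sel))
        for ctx in ("CG", "CHG", "CHH"):
            n_tested = n_meth = 0
            k_sum = n_sum = 0
            for chrom, idx in picked.items():
                pos, ctxs, meth, tested, kk, nn = index[chrom]
                m = idx[(ctxs[idx] == ctx) & tested[idx]]
                n_tested += len(m)
                n_meth += int(meth[m].sum())
                k_sum += int(kk[m].sum())
                n_sum += int(nn[m].sum())
            if weighted:
                level = k_sum / n_sum if n_sum else float("nan")
            else:
                level = n_meth / n_tested if n_tested else float("nan")
            rows.append((key, ctx, n_tested, level))
    return pd.DataFrame(rows, columns=[by, "context", "n_tested", "level"])


@dataclass
class MetageneProfile:
    """Binned methylation around and across gene bodies."""

    upstream_bp: int
    n_body_bins: int
    downstream_bp: int
    bin_bp: int
    levels: dict = field(default_factory=dict)  # context -> vector of bin means
    n_genes: int = 0
    n_skipped: int = 0

    @property
    def n_bins(self) -> int:
        return self.upstream_bp // self.bin_bp + self.n_body_bins + \
            self.downstream_bp // self.bin_bp

    @property
    def body_slice(self) -> slice:
        u = self.upstream_bp // self.bin_bp
        return slice(u, u + self.n_body_bins)


def metagene_profile(
    calls: pd.DataFrame,
    genes,
    upstream_bp: int = 2000,
    n_body_bins: int = 40,
    downstream_bp: int = 2000,
    bin_bp: int = 100,
    pooled: bool = False,
) -> MetageneProfile:
    """Average methylation across gene structures.

    Flanks are binned at fixed ``bin_bp``; the gene body is rescaled to
    ``n_body_bins`` bins.  Minus-strand genes are flipped so bin 0 is always
    the far upstream end.  Per bin the value is the mean over genes of each
    gene's site-methylation fraction in that bin (genes with no tested site
    in a bin contribute nothing there); ``pooled=True`` pools sites across
    genes instead.  Genes shorter than ``n_body_bins`` bases are skipped.
    """
    if upstream_bp % bin_bp or downstream_bp % bin_bp:
        raise ValueError("flank widths must be multiples of bin_bp")
    n_up = upstream_bp // bin_bp
    n_down = downstream_bp // bin_bp
    n_bins = n_up + n_body_bins + n_down
    index = _sites_by_chrom(calls)

    profile = MetageneProfile(upstream_bp, n_body_bins, downstream_bp, bin_bp)
    sums = {c: np.zeros(n_bins) for c in ("CG", "CHG", "CHH")}
    counts = {c: np.zeros(n_bins) for c in ("CG", "CHG", "CHH")}
    n_used = n_skipped = 0

    for g in genes:
        if g.length < n_body_bins:
            n_skipped += 1
            continue
        if g.chrom not in index:
            continue
        n_used += 1
        pos, ctxs, meth, tested, _, _ = index[g.chrom]
        lo = np.searchsorted(pos, g.start - upstream_bp, side="left")
        hi = np.searchsorted(pos, g.end + downstream_bp, side="right")
        if hi == lo:
            continue
        p = pos[lo:hi]
        if g.strand == "+":
            offset = p - g.start  # <0 upstream, [0, len) body
        else:
            offset = g.end - p
        glen = g.length
        bins = np.empty(len(p), dtype=int)
        up = offset < 0
        body = (offset >= 0) & (offset < glen)
        down = offset >= glen
        bins[up] = (offset[up] + upstream_bp) // bin_bp
        bins[body] = n_up + (offset[body] * n_body_bins) // glen
        bins[down] = n_up + n_body_bins + (offset[down] - glen) // bin_bp
        ok = tested[lo:hi] & (bins >= 0) & (bins < n_bins)
        for ctx in ("CG", "CHG", "CHH"):
            m = ok & (ctxs[lo:hi] == ctx)
            if not m.any():
                continue
            b = bins[m]
            meth_b = np.bincount(b, weights=meth[lo:hi][m].astype(float),
                                 minlength=n_bins)
            tot_b = np.bincount(b, minlength=n_bins).astype(float)
            if pooled:
                sums[ctx] += meth_b
                counts[ctx] += tot_b
            else:
                has = tot_b > 0
                sums[ctx][has] += meth_b[has] / tot_b[has]
                counts[ctx][has] += 1

    for ctx in ("CG", "CHG", "CHH"):
        with np.errstate(invalid="ignore", divide="ignore"):
            profile.levels[ctx] = np.where(
                counts[ctx] > 0, sums[ctx] / counts[ctx], np.nan
            )
    profile.n_genes = n_used
    profile.n_skipped = n_skipped
    if n_skipped:
        logger.info("metagene_profile: skipped %d genes shorter than %d bp",
                    n_skipped, n_body_bins)
    return profile


def binned_track(
    values: pd.DataFrame,
    bin_bp: int = 500_000,
    statistic: str = "mean",
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Fixed-width genome track (the 500-kb ring-plot style summary).

    ``values`` needs columns chrom, pos, value (value ignored for
    ``statistic='count'``).  Windows are non-overlapping starting at base 1;
    the last partial window is kept.  Empty bins yield NaN (missing), except
    count bins which are 0 only when the chromosome length is known.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if statistic not in ("mean", "median", "count"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rows = []
    for chrom, grp in values.groupby("chrom"):
        length = (chrom_lengths or {}).get(chrom, int(grp["pos"].max()))
        n_bins = max(1, -(-length // bin_bp))
        idx = (grp["pos"].to_numpy() - 1) // bin_bp
        for b in range(n_bins):
            sel = grp.loc[idx == b]
            if statistic == "count":
                val = float(len(sel))
            elif sel.empty:
                val = float("nan")
            elif statistic == "mean":
                val = float(sel["value"].mean())
            else:
                val = float(sel["value"].median())
            rows.append((chrom, b * bin_bp + 1, min((b + 1) * bin_bp, length), val))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
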