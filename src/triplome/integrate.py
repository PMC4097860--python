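"""Joint methylation/expression views at the gene and triplet level.

Gene-body methylation here means the level over exons plus introns.  The
module provides: expression summaries across gene-body mCG bins (the
hump-shaped "moderate methylation, higher expression" view), a
distribution-free comparison of gene-body levels across the three
sub-genomes, and the 12-variable triplet correlation matrix (three copies x
{FPKM, mCG, mCHG, mCHH}) with a PCA-derived variable ordering as used in
corrgram displays.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTEXTS, SUBGENOMES

logger = logging.getLogger(__name__)


def methylation_expression_bins(
    genes: pd.DataFrame, n_bins: int = 10, normalize: bool = True
) -> pd.DataFrame:
    """Expression summaries per equal-width gene-body mCG bin on [0, 1].

    ``genes`` needs columns ``mCG`` (gene-body level in [0, 1]) and ``fpkm``.
    Expression is ln(FPKM+1), z-scored across genes when ``normalize``.
    Empty bins are reported with count 0.
    """
    if ((genes["mCG"] < 0) | (genes["mCG"] > 1)).any():
        raise ValueError("mCG levels must be in [0, 1]")
    y = np.log1p(genes["fpkm"].to_numpy(dtype=float))
    if normalize and len(y) > 1 and y.std() > 0:
        y = (y - y.mean()) / y.std()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(genes["mCG"], edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = y[idx == b]
        if len(sel):
            q1, med, q3 = np.percentile(sel, [25, 50, 75])
        else:
            q1 = med = q3 = float("nan")
        rows.append((b, edges[b], edges[b + 1], len(sel), med, q1, q3))
    return pd.DataFrame(
        rows,
        columns=["bin", "mCG_lo", "mCG_hi", "count", "median", "q1", "q3"],
    )


def subgenome_methylation_comparison(
    levels: pd.DataFrame, use_anova: bool = False
) -> pd.DataFrame:
    """Compare gene-body methylation distributions across sub-genomes.

    ``levels``: columns subgenome (LF/MF1/MF2), context, level.  Per
    context: median and mean per sub-genome plus a Kruskal-Wallis p-value
    across the three groups (one-way ANOVA with ``use_anova``).  Contexts
    where any sub-genome has < 2 genes skip the test (p = NaN).
    """
    rows = []
    for ctx in CONTEXTS:
        sub = levels[levels["context"] == ctx]
        groups = [
            sub.loc[sub["subgenome"] == g, "level"].dropna().to_numpy()
            for g in SUBGENOMES
        ]
        stats_row = {}
        for g, vals in zip(SUBGENOMES, groups):
            stats_row[f"median_{g}"] = float(np.median(vals)) if len(vals) else float("nan")
            stats_row[f"mean_{g}"] = float(np.mean(vals)) if len(vals) else float("nan")
            stats_row[f"n_{g}"] = len(vals)
        if all(len(v) >= 2 for v in groups):
            if use_anova:
                p = float(stats.f_oneway(*groups).pvalue)
            else:
                try:
                    p = float(stats.kruskal(*groups).pvalue)
                except ValueError:  # all values identical
                    p = 1.0
        else:
            p = float("nan")
        rows.append({"context": ctx, "p_value": p, **stats_row})
    return pd.DataFrame(rows)


def triplet_correlation_matrix(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """12x12 Pearson correlation across triplets, with PCA angular ordering.

    ``profiles`` has one row per triplet and one column per variable
    (copy x {fpkm, mCG, mCHG, mCHH}); at least 3 triplets are required.
    Zero-variance variables are excluded (logged).  The ordering is the
    angular order of the variables in the plane of the first two principal
    components of the correlation matrix, the convention corrgram-style
    displays use to place similar variables adjacently; the sign of each
    component is fixed so its first nonzero loading is non-negative, making
    the ordering deterministic.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 triplets")
    variances = profiles.var(axis=0)
    dropped = list(profiles.columns[variances == 0])
    if dropped:
        logger.info("excluding zero-variance variables: %s", dropped)
    prof = profiles.drop(columns=dropped)
    corr = prof.corr(method="pearson")

    eigval, eigvec = np.linalg.eigh(corr.to_numpy())
    order_desc = np.argsort(eigval)[::-1]
    pcs = eigvec[:, order_desc[:2]]
    for j in range(pcs.shape[1]):
        nz = np.flatnonzero(np.abs(pcs[:, j]) > 1e-12)
        if len(nz) and pcs[nz[0], j] < 0:
            pcs[:, j] = -pcs[:, j]
    angles = np.arctan2(pcs[:, 1], pcs[:, 0])
    ordering = [corr.columns[i] for i in np.argsort(angles, kind="stable")]
    return corr, ordering


def gene_body_levels(
    calls: pd.DataFrame, genes, min_depth: int = 1
) -> pd.DataFrame:
    """Per-gene gene-body (exon+intron) methylation level per context.

    Level = methylated/tested site fraction within the gene's exons and
    introns; genes with no tested sites in a context get NaN.
    """
    from .summaries import _sites_by_chrom
    from .methcall import STATUS_METHYLATED, STATUS_UNTESTED  # noqa: F401

    index = _sites_by_chrom(calls)
    rows = []
    for g in genes:
        ivs = sorted(g.parts.get("exon", []) + g.parts.get("intron", []))
        if not ivs or g.chrom not in index:
            rows.append((g.gene_id, *[float("nan")] * 3))
            continue
        pos, ctxs, meth, tested, _, _ = index[g.chrom]
        sel = []
        for s, e in ivs:
            lo = np.searchsorted(pos, s, "left")
            hi = np.searchsorted(pos, e, "right")
            if hi > lo:
                sel.append(np.arange(lo, hi))
        if not sel:
            rows.append((g.gene_id, *[float("nan")] * 3))
            continue
        idx = np.unique(np.concatenate(sel))
        vals = []
        for ctx in CONTEXTS:
            m = idx[(ctxs[idx] == ctx) & tested[idx]]
            vals.append(float(meth[m].mean()) if len(m) else float("nan"))
        rows.append((g.gene_id, *vals))
    return pd.DataFrame(rows, columns=["gene_id", "mCG", "mCHG", "mCHH"])
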