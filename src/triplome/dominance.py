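"""Sub-genome dominance and functional diversification of retained triplets.

A fully retained triplet is one ancestral gene surviving in all three
sub-genome copies (LF/MF1/MF2), giving an unreplicated 3 (sub-genome, G) x
4 (tissue, T) table of FPKM values.  On the ln(FPKM+1) scale the G x T
interaction cannot be separated from error without replication, so the
one-degree-of-freedom test for non-additivity (Tukey) is used: it tests an
interaction of the multiplicative form lambda * G_i * T_j against the
additive model.  Triplets with a significant interaction are summarised by
which sub-genome copy is most highly expressed; an excess of LF is the
residual signature of genome dominance.

Functional diversification is assessed by average-linkage hierarchical
clustering of per-gene tissue profiles with distance 1 - Pearson r, and by
asking how often the three copies of a triplet land in different clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .config import SUBGENOMES

logger = logging.getLogger(__name__)

TUKEY_TOL = 1e-12  # relative tolerance for degenerate denominators


def transform_expression(fpkm: np.ndarray) -> np.ndarray:
    """y = ln(FPKM + 1), elementwise; FPKM must be non-negative."""
    fpkm = np.asarray(fpkm, dtype=float)
    if (fpkm < 0).any():
        raise ValueError("negative FPKM value")
    return np.log1p(fpkm)


def highest_subgenome(y: np.ndarray) -> tuple[str, bool]:
    """Row (sub-genome) with the highest mean over tissues.

    Ties are broken in the fixed order LF > MF1 > MF2 and flagged.
    """
    y = np.asarray(y, dtype=float)
    means = y.mean(axis=1)
    best = int(np.argmax(means))  # argmax takes the first of tied maxima
    tie = bool((means == means[best]).sum() > 1)
    return SUBGENOMES[best], tie


@dataclass
class TukeyResult:
    triplet_id: str
    highest_subgenome: str
    F_statistic: float
    p_value: float
    degenerate_flag: bool
    tie_flag: bool = False


def tukey_interaction_test(y: np.ndarray, triplet_id: str = "") -> TukeyResult:
    """One-degree-of-freedom test for non-additivity on a 3 x 4 table.

    With row means yi., column means y.j and grand mean y..:

        N          = sum_ij y_ij (yi. - y..)(y.j - y..)
        SS_nonadd  = N^2 / [ sum_i (yi.-y..)^2 * sum_j (y.j-y..)^2 ]
        SS_resid   = sum_ij (y_ij - yi. - y.j + y..)^2
        F          = SS_nonadd / [ (SS_resid - SS_nonadd) / 5 ]   on (1, 5) df

    Degenerate tables (zero row or column variance, or residual entirely
    absorbed by the non-additivity term) are reported with p = 1 and the
    degenerate flag set.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (3, 4):
        raise ValueError(f"expected a 3x4 table, got {y.shape}")
    label, tie = highest_subgenome(y)

    row_dev = y.mean(axis=1) - y.mean()
    col_dev = y.mean(axis=0) - y.mean()
    ss_rows = float((row_dev**2).sum())
    ss_cols = float((col_dev**2).sum())
    resid = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    ss_resid = float((resid**2).sum())
    scale = max(float((y**2).sum()), 1.0)

    if ss_rows <= TUKEY_TOL * scale or ss_cols <= TUKEY_TOL * scale:
        return TukeyResult(triplet_id, label, 0.0, 1.0, True, tie)

    n_stat = float((y * np.outer(row_dev, col_dev)).sum())
    ss_nonadd = n_stat**2 / (ss_rows * ss_cols)
    denom = ss_resid - ss_nonadd
    if denom <= TUKEY_TOL * scale:
        return TukeyResult(triplet_id, label, 0.0, 1.0, True, tie)
    f_stat = ss_nonadd / (denom / 5.0)
    p = float(stats.f.sf(f_stat, 1, 5))
    return TukeyResult(triplet_id, label, float(f_stat), p, False, tie)


def test_triplets(triplets, fpkm_matrices) -> list[TukeyResult]:
    """Convenience: transform and test a collection of triplet tables."""
    return [
        tukey_interaction_test(transform_expression(m), triplet_id=str(t))
        for t, m in zip(triplets, fpkm_matrices)
    ]


def dominance_summary(results: list[TukeyResult], alpha: float = 0.05) -> dict:
    """Counts of significant triplets and sub-genome shares among them."""
    sig = [r for r in results if r.p_value < alpha]
    shares = {g: 0.0 for g in SUBGENOMES}
    for r in sig:
        shares[r.highest_subgenome] += 1
    n_sig = len(sig)
    if n_sig:
        shares = {g: c / n_sig for g, c in shares.items()}
    return {
        "n_total": len(results),
        "n_significant": n_sig,
        "fraction_significant": n_sig / len(results) if results else 0.0,
        "shares": shares,
    }


def cumulative_dominance_curve(results: list[TukeyResult]) -> pd.DataFrame:
    """Cumulative sub-genome shares along the p-value ranking.

    Triplets are sorted by ascending Tukey p (ties by triplet_id); at each
    rank the cumulative proportion of each highest-expression label among
    the triplets seen so far is reported.
    """
    ordered = sorted(results, key=lambda r: (r.p_value, r.triplet_id))
    rows = []
    counts = {g: 0 for g in SUBGENOMES}
    for rank, r in enumerate(ordered, 1):
        counts[r.highest_subgenome] += 1
        rows.append(
            (rank, r.triplet_id, r.p_value)
            + tuple(counts[g] / rank for g in SUBGENOMES)
        )
    return pd.DataFrame(
        rows, columns=["rank", "triplet_id", "p_value", *SUBGENOMES]
    )


# ---------------------------------------------------------------------------
# Expression-profile clustering
# ---------------------------------------------------------------------------

def correlation_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - Pearson r between gene tissue profiles; d in [0, 2]."""
    profiles = np.asarray(profiles, dtype=float)
    if (profiles.std(axis=1) == 0).any():
        raise ValueError("zero-variance profile; filter before clustering")
    d = 1.0 - np.corrcoef(profiles)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def cluster_expression_profiles(
    profiles: np.ndarray, gene_ids: list[str], k: int = 15
) -> tuple[pd.DataFrame, np.ndarray]:
    """Average-linkage clustering on 1 - r; cut to exactly ``k`` clusters.

    Genes with zero variance across tissues are filtered (and counted in the
    log) before clustering.  Returns (assignments, linkage matrix); the cut
    takes cluster memberships after n - k merges, which always yields
    exactly k clusters.  Cluster indices are 1..k in order of first gene
    occurrence, making the labelling deterministic given input order.
    """
    profiles = np.asarray(profiles, dtype=float)
    keep = profiles.std(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance genes before clustering", n_dropped)
    profiles = profiles[keep]
    ids = [g for g, kflag in zip(gene_ids, keep) if kflag]
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds number of clusterable genes ({n})")
    dist = correlation_distance_matrix(profiles)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = _cut_to_k(z, n, k)
    assignments = pd.DataFrame({"gene_id": ids, "cluster_index": labels})
    return assignments, z


def _cut_to_k(z: np.ndarray, n: int, k: int) -> np.ndarray:
    """Membership after the first n-k merges of a linkage matrix."""
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    clusters = {i: i for i in range(n)}  # linkage node id -> representative
    for step in range(n - k):
        a, b = int(z[step, 0]), int(z[step, 1])
        ra, rb = find(clusters[a]), find(clusters[b])
        parent[rb] = ra
        clusters[n + step] = ra
    roots = [find(i) for i in range(n)]
    index_of = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in index_of:
            index_of[r] = len(index_of) + 1
        labels[i] = index_of[r]
    return labels


def triplet_separation(
    assignments: pd.DataFrame, triplets: pd.DataFrame
) -> dict:
    """How often the three copies of a triplet fall in different clusters.

    A triplet is *separated* when its clustered members do not all share one
    cluster.  Reports the fraction of clustered triplet-member genes that
    belong to separated triplets (primary) and the fraction of triplets
    separated (secondary).  Triplets with fewer than two clustered members
    cannot be assessed and are excluded.
    """
    cluster_of = dict(
        zip(assignments["gene_id"], assignments["cluster_index"])
    )
    n_trip = n_sep = 0
    n_genes = n_genes_sep = 0
    for _, row in triplets.iterrows():
        members = [
            cluster_of[g]
            for g in (row["lf_gene"], row["mf1_gene"], row["mf2_gene"])
            if g in cluster_of
        ]
        if len(members) < 2:
            continue
        n_trip += 1
        n_genes += len(members)
        if len(set(members)) > 1:
            n_sep += 1
            n_genes_sep += len(members)
    return {
        "n_triplets": n_trip,
        "fraction_genes_separated": n_genes_sep / n_genes if n_genes else 0.0,
        "fraction_triplets_separated": n_sep / n_trip if n_trip else 0.0,
    }
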