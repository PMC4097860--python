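"""Collinear anchor chaining, sub-genome assignment and fractionation stats.

A triplicated genome carries each ancestral block in up to three collinear
copies.  Starting from protein homology hits against the ancestral (outgroup)
proteome, the stages are:

1. filter hits (E-value cutoff plus a margin below each query's best bit
   score),
2. chain collinear anchors per chromosome pair with a longest-path dynamic
   programme over a DAG (gap-penalised, bounded gene-index gaps, both
   orientations, best-first extraction so each anchor serves one chain),
3. resolve queries claimed by several chains in favour of the stronger
   chain,
4. group chain copies by ancestral block and rank them by retained-anchor
   fraction into LF > MF1 > MF2 (or apply a supplied partition),
5. assemble the syntelog table and compute retention statistics, and
6. classify genes as syntenic / non-syntenic / species-specific with a
   tandem-duplicate flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SUBGENOMES


# ---------------------------------------------------------------------------
# Hit filtering
# ---------------------------------------------------------------------------

def filter_hits(
    hits: pd.DataFrame,
    evalue_max: float = 1e-20,
    bitscore_margin: float = 0.4,
    quantile_mode: bool = False,
) -> pd.DataFrame:
    """Keep strong hits per query.

    Default reading: E-value <= ``evalue_max`` and bit score within the top
    ``bitscore_margin`` fraction below the query's best hit, i.e.
    bit >= (1 - margin) * best.  ``quantile_mode=True`` instead keeps the
    top ``bitscore_margin`` quantile of a query's hits (the alternative
    reading of the same rule).
    """
    ok_e = hits["evalue"] <= evalue_max
    sub = hits[ok_e]
    if sub.empty:
        return sub.copy()
    if quantile_mode:
        thresh = sub.groupby("qseqid")["bitscore"].transform(
            lambda s: s.quantile(1.0 - bitscore_margin)
        )
    else:
        best = sub.groupby("qseqid")["bitscore"].transform("max")
        thresh = (1.0 - bitscore_margin) * best
    return sub[sub["bitscore"] >= thresh].copy()


# ---------------------------------------------------------------------------
# Anchor chaining
# ---------------------------------------------------------------------------

@dataclass
class Anchor:
    query_index: int
    target_index: int
    score: float = 1.0
    query_gene: str = ""
    target_gene: str = ""


@dataclass
class SyntenicChain:
    anchors: list
    score: float
    orientation: str  # "same" | "inverted"
    block_label: str = ""
    subgenome_label: str = "unassigned"
    query_chrom: str = ""

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def query_genes(self) -> list[str]:
        return [a.query_gene for a in self.anchors]


def _chain_score(anchors: list[Anchor], gap_penalty: float) -> float:
    score = sum(a.score for a in anchors)
    for a, b in zip(anchors, anchors[1:]):
        gaps = abs(b.query_index - a.query_index) - 1
        gaps += abs(b.target_index - a.target_index) - 1
        score -= gap_penalty * gaps
    return score


def _best_chain_dp(
    anchors: list[Anchor],
    gap_penalty: float,
    max_gap_genes: int,
    orientation: str,
    min_anchors: int,
) -> tuple[list[int], float]:
    """Highest-scoring chain with at least ``min_anchors`` anchors, via DP.

    The state is (anchor, chain length capped at ``min_anchors``): the best
    short chain is not necessarily a prefix of the best valid chain, so the
    length constraint must be part of the state, not a post-filter.
    """
    sign = 1 if orientation == "same" else -1
    cap = max(min_anchors, 1)
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].query_index, sign * anchors[i].target_index),
    )
    neg = float("-inf")
    dp = {i: [neg] * (cap + 1) for i in order}
    prev: dict[tuple, tuple | None] = {}
    for oi, i in enumerate(order):
        ai = anchors[i]
        dp[i][1] = ai.score
        prev[(i, 1)] = None
        # predecessors must lie within max_gap_genes on the query axis, so
        # only a bounded window of the query-sorted order can qualify
        for oj in range(oi - 1, -1, -1):
            j = order[oj]
            aj = anchors[j]
            dq = ai.query_index - aj.query_index
            if dq > max_gap_genes:
                break
            dt = sign * (ai.target_index - aj.target_index)
            if dq < 1 or dt < 1 or dt > max_gap_genes:
                continue
            trans = ai.score - gap_penalty * ((dq - 1) + (dt - 1))
            for c in range(1, cap + 1):
                if dp[j][c] == neg:
                    continue
                c2 = min(c + 1, cap)
                cand = dp[j][c] + trans
                if cand > dp[i][c2] + 1e-12:
                    dp[i][c2] = cand
                    prev[(i, c2)] = (j, c)
    best_end, best_score = None, neg
    for i in order:
        if dp[i][cap] > best_score + 1e-12:
            best_score = dp[i][cap]
            best_end = i
    if best_end is None:
        return [], neg
    path = []
    state: tuple | None = (best_end, cap)
    while state is not None:
        path.append(state[0])
        state = prev[state]
    path.reverse()
    return path, best_score


def chain_anchors(
    anchors: list[Anchor],
    gap_penalty: float = 0.25,
    max_gap_genes: int = 10,
    min_anchors: int = 5,
    query_chrom: str = "",
) -> list[SyntenicChain]:
    """Best-first extraction of collinear chains on one chromosome pair.

    Repeatedly take the highest-scoring chain (either orientation) among
    the unused anchors; stop when no remaining chain reaches
    ``min_anchors``.  Chain score = sum of anchor scores minus
    ``gap_penalty`` per skipped gene on either axis; transitions may skip at
    most ``max_gap_genes`` gene positions on each axis.
    """
    remaining = list(anchors)
    chains = []
    while len(remaining) >= min_anchors:
        candidates = []
        for orient in ("same", "inverted"):
            path, score = _best_chain_dp(
                remaining, gap_penalty, max_gap_genes, orient, min_anchors
            )
            if len(path) >= min_anchors:
                candidates.append((score, orient, path))
        if not candidates:
            break
        # higher score wins; ties favour "inverted" last, then longer chains
        candidates.sort(key=lambda c: (-c[0], c[1] != "same", -len(c[2])))
        score, orient, path = candidates[0]
        chosen = [remaining[i] for i in path]
        chains.append(SyntenicChain(chosen, score, orient, query_chrom=query_chrom))
        used = set(path)
        remaining = [a for i, a in enumerate(remaining) if i not in used]
    return chains


def resolve_chain_overlaps(
    chains: list[SyntenicChain],
    gap_penalty: float = 0.25,
    min_anchors: int = 5,
) -> list[SyntenicChain]:
    """Each query gene may anchor only its highest-scoring chain.

    Anchors for a query that appears in several chains are removed from all
    but the strongest chain; chains falling below ``min_anchors`` are
    deleted.  Scores are recomputed after removal.
    """
    order = sorted(
        range(len(chains)), key=lambda i: (-chains[i].score, i)
    )
    claimed: dict[str, int] = {}
    for i in order:
        for g in chains[i].query_genes:
            claimed.setdefault(g, i)
    out = []
    for i, ch in enumerate(chains):
        kept = [a for a in ch.anchors if claimed[a.query_gene] == i]
        if len(kept) < min_anchors:
            continue
        out.append(
            SyntenicChain(
                kept, _chain_score(kept, gap_penalty), ch.orientation,
                ch.block_label, ch.subgenome_label, ch.query_chrom,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Block / sub-genome assignment and the syntelog table
# ---------------------------------------------------------------------------

def assign_blocks_and_subgenomes(
    chains: list[SyntenicChain],
    block_of: dict,
    block_sizes: dict,
    partition: dict | None = None,
) -> tuple[list[SyntenicChain], pd.DataFrame]:
    """Label chain copies per ancestral block and build the syntelog table.

    ``block_of`` maps ancestral gene -> block id; ``block_sizes`` maps block
    id -> number of ancestral genes in the block.  Chains sharing a block
    and a query chromosome form one *copy* of the block (a copy may be
    fragmented into several chains).  Per block, up to three copies are
    ranked by combined retained-anchor fraction; rank 1 -> LF, 2 -> MF1,
    3 -> MF2 (ties by combined score, then first chain index).  Extra
    copies beyond three stay unassigned.  A ``partition`` mapping
    (block, rank) -> sub-genome overrides the default ranking labels when a
    curated genome-wide partition is available.
    """
    for ch in chains:
        blocks = [block_of.get(a.target_gene) for a in ch.anchors]
        blocks = [b for b in blocks if b is not None]
        ch.block_label = max(set(blocks), key=blocks.count) if blocks else ""

    by_copy: dict[tuple, list[int]] = {}
    for i, ch in enumerate(chains):
        if ch.block_label:
            key = (ch.block_label, ch.query_chrom or f"chain{i}")
            by_copy.setdefault(key, []).append(i)

    by_block: dict[str, list[tuple]] = {}
    for key in by_copy:
        by_block.setdefault(key[0], []).append(key)

    for block, copies in by_block.items():
        size = block_sizes.get(block, 0)
        ranked = sorted(
            copies,
            key=lambda key: (
                -(sum(len(chains[i]) for i in by_copy[key]) / size if size else 0.0),
                -sum(chains[i].score for i in by_copy[key]),
                min(by_copy[key]),
            ),
        )
        for rank, key in enumerate(ranked):
            if partition is not None and (block, rank) in partition:
                label = partition[(block, rank)]
            elif rank < 3:
                label = SUBGENOMES[rank]
            else:
                label = "unassigned"
            for i in by_copy[key]:
                chains[i].subgenome_label = label

    rows: dict[str, dict] = {}
    seen_query: set[str] = set()
    for ch in chains:
        if ch.subgenome_label not in SUBGENOMES:
            continue
        for a in ch.anchors:
            if a.query_gene in seen_query:
                raise ValueError(
                    f"query gene {a.query_gene} in multiple chains; "
                    "run resolve_chain_overlaps first"
                )
            seen_query.add(a.query_gene)
            row = rows.setdefault(
                a.target_gene, {g: None for g in SUBGENOMES}
            )
            if row[ch.subgenome_label] is None:
                row[ch.subgenome_label] = a.query_gene
    table = pd.DataFrame(
        [
            {"ancestral_gene": t, **r}
            for t, r in sorted(rows.items())
        ],
        columns=["ancestral_gene", *SUBGENOMES],
    )
    return chains, table


def retention_stats(
    syntelog: pd.DataFrame, n_ancestral: int | None = None
) -> dict:
    """Per-sub-genome retention percentage and the fully retained triplets.

    ``n_ancestral`` is the total number of ancestral genes considered; by
    default the number of rows (the table is then assumed to list every
    ancestral gene, retained or not).
    """
    if syntelog.empty:
        raise ValueError("empty syntelog table")
    if n_ancestral is None:
        n_ancestral = len(syntelog)
    retention = {
        g: 100.0 * syntelog[g].notna().sum() / n_ancestral for g in SUBGENOMES
    }
    full = syntelog[[*SUBGENOMES]].notna().all(axis=1)
    triplets = syntelog.loc[full, ["ancestral_gene", *SUBGENOMES]].copy()
    triplets = triplets.rename(
        columns={"LF": "lf_gene", "MF1": "mf1_gene", "MF2": "mf2_gene"}
    )
    triplets.insert(0, "triplet_id", triplets.pop("ancestral_gene"))
    return {"retention": retention, "triplets": triplets.reset_index(drop=True)}


# ---------------------------------------------------------------------------
# Gene categories
# ---------------------------------------------------------------------------

def classify_gene_category(
    genes: pd.DataFrame,
    chains: list[SyntenicChain],
    block_intervals: pd.DataFrame | None,
    hits: pd.DataFrame,
    tandem_max_separation: int = 5,
) -> pd.DataFrame:
    """Syntenic / non-syntenic / species-specific classes plus tandem flag.

    ``genes`` needs gene_id, chrom and a gene-order index column ``order``.
    Anchor members are syntenic; genes with no homology hit at all are
    species-specific; genes with homology but no syntenic position are
    non-syntenic (whether inside or outside block intervals; the
    ``in_block`` column records which).  Two genes hitting a common target
    on the same chromosome with at most ``tandem_max_separation`` intervening
    genes are flagged tandem (a flag, not a category).
    """
    anchor_queries = {a.query_gene for ch in chains for a in ch.anchors}
    with_hit = set(hits["qseqid"].unique())

    in_block = {}
    if block_intervals is not None:
        for _, row in genes.iterrows():
            sub = block_intervals[block_intervals["chrom"] == row["chrom"]]
            in_block[row["gene_id"]] = bool(
                ((sub["start"] <= row["order"]) & (row["order"] <= sub["end"])).any()
            )

    # tandem: same chrom, shared target, close in gene order
    tandem: set[str] = set()
    merged = hits.merge(genes[["gene_id", "chrom", "order"]],
                        left_on="qseqid", right_on="gene_id")
    for (_, _), grp in merged.groupby(["sseqid", "chrom"]):
        orders = np.sort(grp["order"].unique())
        close = np.diff(orders) <= tandem_max_separation + 1
        for i, flag in enumerate(close):
            if flag:
                pair = grp[grp["order"].isin(orders[i:i + 2])]["gene_id"]
                tandem.update(pair)

    rows = []
    for _, row in genes.iterrows():
        g = row["gene_id"]
        if g in anchor_queries:
            cat = "syntenic"
        elif g not in with_hit:
            cat = "species_specific"
        else:
            cat = "non_syntenic"
        rows.append(
            (g, cat, g in tandem, in_block.get(g, None))
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "category", "tandem", "in_block"]
    )
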