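"""Synthetic-data generators with known ground truth.

Every downstream stage of the package can be exercised on data from this
module: a random genome with annotated gene models, a triplicated gene
complement with biased retention across the three sub-genome copies,
per-cytosine bisulfite counts with a Poisson depth and a small
non-conversion error (plus an unmethylated spike-in control), an
additive-plus-interaction expression model on the ln(FPKM+1) scale, and a
half-tetrad mapping population derived from first-division-restitution
(FDR) unreduced gametes.

A single integer seed makes every generator bit-for-bit reproducible;
independent streams are derived per generator so the stages can be run in
any combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CONTEXTS,
    SUBGENOMES,
    TISSUES,
    SimulationConfig,
)
from .io import GeneModel, derive_flanks_and_introns
from .synteny import Anchor

_STREAMS = {
    "genome": 1,
    "methylome": 2,
    "fractionation": 3,
    "expression": 4,
    "meiosis": 5,
}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

def simulate_genome_and_genes(
    config: SimulationConfig,
) -> tuple[dict, list[GeneModel]]:
    """Random genome at the configured GC plus non-overlapping gene models.

    Genes are laid out with promoter/downstream headroom; each has a
    5' UTR, 1-4 exons with intervening introns, and a 3' UTR, on a random
    strand.  Raises if a chromosome cannot hold its share of genes.
    """
    config.validate()
    rng = _rng(config, "genome")
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = {}
    for c in range(config.n_chromosomes):
        seq = rng.choice(np.array(list("ACGT")), size=config.chrom_length_bp, p=probs)
        genome[f"chr{c + 1}"] = "".join(seq)

    genes: list[GeneModel] = []
    per_chrom = np.full(config.n_chromosomes, config.n_ancestral_genes // config.n_chromosomes)
    per_chrom[: config.n_ancestral_genes % config.n_chromosomes] += 1
    margin = 2100  # room for promoter/downstream windows
    min_gap = 200
    gene_counter = 0
    for ci, chrom in enumerate(genome):
        n_genes = int(per_chrom[ci])
        if n_genes == 0:
            continue
        lengths = rng.integers(900, 3001, size=n_genes)
        needed = 2 * margin + lengths.sum() + (n_genes - 1) * min_gap
        if needed > config.chrom_length_bp:
            raise ValueError(
                f"{chrom}: too short ({config.chrom_length_bp} bp) for "
                f"{n_genes} genes (need >= {needed} bp)"
            )
        slack = config.chrom_length_bp - needed
        extra = rng.multinomial(slack, np.full(n_genes + 1, 1 / (n_genes + 1)))
        pos = margin + extra[0] + 1  # 1-based start of first gene
        for gi in range(n_genes):
            gene_counter += 1
            start, end = int(pos), int(pos + lengths[gi] - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel(
                gene_id=f"gene{gene_counter:05d}", chrom=chrom,
                strand=strand, start=start, end=end,
            )
            g.parts.update(_gene_parts(rng, start, end, strand))
            derive_flanks_and_introns(g, chrom_length=config.chrom_length_bp)
            genes.append(g)
            pos = end + 1 + min_gap + extra[gi + 1]
    return genome, genes


def _gene_parts(rng, start, end, strand) -> dict:
    """UTR / exon layout inside [start, end]; intron gaps are derived."""
    length = end - start + 1
    utr5 = int(rng.integers(80, 201))
    utr3 = int(rng.integers(80, 201))
    body = length - utr5 - utr3
    n_exons = int(rng.integers(1, 5))
    # alternate exon/intron; every piece at least 60 bp
    n_pieces = 2 * n_exons - 1
    if body < 60 * n_pieces:
        n_exons = max(1, body // 180)
        n_pieces = 2 * n_exons - 1
    cuts = rng.multinomial(body - 60 * n_pieces, np.full(n_pieces, 1 / n_pieces))
    sizes = 60 + cuts
    five = (start, start + utr5 - 1)
    three = (end - utr3 + 1, end)
    exons, introns = [], []
    pos = start + utr5
    for i, size in enumerate(sizes):
        iv = (pos, pos + int(size) - 1)
        (exons if i % 2 == 0 else introns).append(iv)
        pos += int(size)
    if strand == "-":
        five, three = three, five
    return {"five_prime_UTR": [five], "exon": exons, "three_prime_UTR": [three]}


# ---------------------------------------------------------------------------
# Fractionation / synteny truth
# ---------------------------------------------------------------------------

@dataclass
class FractionationTruth:
    syntelog: pd.DataFrame          # ancestral_gene x LF/MF1/MF2 (NaN = lost)
    hits: pd.DataFrame              # qseqid, sseqid, bitscore, evalue
    anchors: dict = field(default_factory=dict)   # query chrom -> [Anchor]
    block_of: dict = field(default_factory=dict)  # ancestral gene -> block id
    block_sizes: dict = field(default_factory=dict)
    subgenome_of_chrom: dict = field(default_factory=dict)  # query chrom -> truth label


def simulate_fractionation(
    config: SimulationConfig,
    n_blocks: int = 24,
    decoy_rate: float = 0.1,
) -> FractionationTruth:
    """Biased retention of a triplicated ancestral gene set.

    Each ancestral gene is retained independently in sub-genome g with
    probability ``retention_probs[g]``.  Retained copies are placed
    collinearly, one query chromosome per sub-genome, with ancestral
    blocks shuffled (and randomly inverted) per sub-genome so collinear
    chains break at block boundaries.  The homology table contains the true
    anchors (high bit score, tiny E-value) plus decoy hits.
    """
    config.validate()
    rng = _rng(config, "fractionation")
    n = config.n_ancestral_genes
    n_blocks = min(n_blocks, n) if n else 0
    block_names = [chr(ord("A") + i % 26) + ("" if i < 26 else str(i // 26)) for i in range(n_blocks)]

    block_idx = np.repeat(np.arange(max(n_blocks, 1)), -(-n // max(n_blocks, 1)))[:n]
    ancestral = [f"anc_{block_names[b]}_{i:05d}" for i, b in enumerate(block_idx)]
    block_of = {g: block_names[b] for g, b in zip(ancestral, block_idx)}
    block_sizes = {
        name: int((block_idx == i).sum()) for i, name in enumerate(block_names)
    }

    retained = {
        g: rng.random(n) < p for g, p in zip(SUBGENOMES, config.retention_probs)
    }
    table = pd.DataFrame({"ancestral_gene": ancestral})
    anchors: dict[str, list[Anchor]] = {}
    hit_rows = []
    subgenome_of_chrom = {}
    for si, sub in enumerate(SUBGENOMES):
        chrom = f"q_{sub}"
        subgenome_of_chrom[chrom] = sub
        keep = retained[sub]
        ids = np.array([f"bo_{sub}_{i:05d}" if keep[i] else None for i in range(n)],
                       dtype=object)
        table[sub] = ids
        # shuffle block order, invert some blocks, to delimit chains; a
        # query-index spacer (> any sensible max gap) models the
        # non-syntenic genes that interrupt real block boundaries
        order = rng.permutation(n_blocks) if n_blocks else []
        query_order = []
        block_spacer = 25
        qidx0 = 0
        positions = []
        for b in order:
            members = [i for i in range(n) if block_idx[i] == b and keep[i]]
            if rng.random() < 0.4:
                members = members[::-1]
            for k, i in enumerate(members):
                query_order.append(i)
                positions.append(qidx0 + k)
            qidx0 += len(members) + block_spacer
        alist = []
        for qidx, i in zip(positions, query_order):
            bit = float(rng.uniform(200, 500))
            ev = float(10.0 ** rng.uniform(-180, -50))
            alist.append(
                Anchor(qidx, int(i), 1.0, str(ids[i]), ancestral[i])
            )
            hit_rows.append((str(ids[i]), ancestral[i], bit, ev))
            if rng.random() < decoy_rate:
                j = int(rng.integers(0, n))
                hit_rows.append(
                    (str(ids[i]), ancestral[j], float(rng.uniform(40, 110)),
                     float(10.0 ** rng.uniform(-30, -5)))
                )
        anchors[chrom] = alist
    hits = pd.DataFrame(hit_rows, columns=["qseqid", "sseqid", "bitscore", "evalue"])
    return FractionationTruth(
        syntelog=table, hits=hits, anchors=anchors, block_of=block_of,
        block_sizes=block_sizes, subgenome_of_chrom=subgenome_of_chrom,
    )


# ---------------------------------------------------------------------------
# Methylome counts
# ---------------------------------------------------------------------------

def _cytosine_scan(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All cytosine positions (1-based), strands and contexts in ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out_pos, out_strand, out_ctx = [], [], []
    # plus strand: C at i; CG if i+1 is G; CHG if i+2 is G
    c = arr == b"C"
    g = arr == b"G"
    nxt_g = np.append(g[1:], False)
    nxt2_g = np.append(g[2:], [False, False])
    plus_ctx = np.where(nxt_g, "CG", np.where(nxt2_g, "CHG", "CHH"))
    idx = np.flatnonzero(c)
    out_pos.append(idx + 1)
    out_strand.append(np.full(len(idx), "+"))
    out_ctx.append(plus_ctx[idx])
    # minus strand: C is G on forward; neighbours to the left, complemented
    prev_c = np.insert(c[:-1], 0, False)
    prev2_c = np.insert(c[:-2], 0, [False, False])
    minus_ctx = np.where(prev_c, "CG", np.where(prev2_c, "CHG", "CHH"))
    idx = np.flatnonzero(g)
    out_pos.append(idx + 1)
    out_strand.append(np.full(len(idx), "-"))
    out_ctx.append(minus_ctx[idx])
    return (
        np.concatenate(out_pos),
        np.concatenate(out_strand),
        np.concatenate(out_ctx),
    )


def _part_labels(length: int, genes: list[GeneModel], chrom: str) -> np.ndarray:
    """Per-position gene-part label (or '' outside annotated parts)."""
    labels = np.full(length, "", dtype=object)
    order = ("downstream", "promoter", "three_prime_UTR", "five_prime_UTR",
             "intron", "exon")  # later wins: genic parts take priority
    for part in order:
        for g in genes:
            if g.chrom != chrom:
                continue
            for s, e in g.parts.get(part, []):
                labels[max(s - 1, 0): e] = part
    return labels


def simulate_methylome_counts(
    config: SimulationConfig,
    genome: dict,
    genes: list[GeneModel] | None = None,
    mosaic: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cytosine counts for the genome and the unmethylated control.

    Per cytosine the context comes from the sequence; the true methylation
    state is Bernoulli with the context level (optionally overridden per
    gene part via ``config.feature_meth_levels``), depth is
    Poisson(``depth_lambda``) per strand, and observed methylated reads are
    Binomial(depth, m + (1-m)*e) with ``e`` the non-conversion error.
    ``mosaic=True`` uses the level itself as a continuous per-site
    methylation fraction instead of a 0/1 state.  Control (spike-in) sites
    are truly unmethylated throughout.  Zero-coverage sites are emitted.
    """
    config.validate()
    rng = _rng(config, "methylome")
    e = config.nonconversion_e

    frames = []
    for chrom, seq in genome.items():
        pos, strand, ctx = _cytosine_scan(seq)
        level = np.array([config.true_meth_levels.get(c, 0.0) for c in ctx])
        if config.feature_meth_levels and genes:
            parts = _part_labels(len(seq), genes, chrom)[pos - 1]
            for part, ctx_levels in config.feature_meth_levels.items():
                for c, lvl in ctx_levels.items():
                    level[(parts == part) & (ctx == c)] = lvl
        if mosaic:
            m = level
        else:
            m = (rng.random(len(pos)) < level).astype(float)
        depth = rng.poisson(config.depth_lambda, size=len(pos))
        p_read = m + (1.0 - m) * e
        k = rng.binomial(depth, p_read)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(depth > 0, k / np.where(depth > 0, depth, 1), np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": strand, "context": ctx,
            "ratio": ratio, "eff_CT_count": depth, "C_count": k,
            "true_m": m,
        }))
    sites = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "context", "ratio",
                 "eff_CT_count", "C_count", "true_m"])

    lam_seq = "".join(rng.choice(np.array(list("ACGT")), size=config.lambda_length_bp))
    lpos, lstrand, lctx = _cytosine_scan(lam_seq)
    ldepth = rng.poisson(config.depth_lambda, size=len(lpos))
    lk = rng.binomial(ldepth, e)
    with np.errstate(divide="ignore", invalid="ignore"):
        lratio = np.where(ldepth > 0, lk / np.where(ldepth > 0, ldepth, 1), np.nan)
    lambda_sites = pd.DataFrame({
        "chrom": "lambda", "pos": lpos, "strand": lstrand, "context": lctx,
        "ratio": lratio, "eff_CT_count": ldepth, "C_count": lk,
        "true_m": 0.0,
    })
    return sites, lambda_sites


# ---------------------------------------------------------------------------
# Expression triplets
# ---------------------------------------------------------------------------

def simulate_expression_triplets(
    config: SimulationConfig,
    triplets: pd.DataFrame,
) -> dict:
    """FPKM tables for fully retained triplets under the G + T (+ GxT) model.

    On the ln(FPKM+1) scale: y_ij = mu + G_i + T_j + GT_ij + eps_ij with the
    configured interaction mode, plus ``lf_shift_delta`` on the LF row.
    Back-transformed FPKM = exp(y) - 1 clipped at 0.  Returns
    {triplet_id: 3x4 array} with rows LF/MF1/MF2 and columns the four
    tissues.
    """
    config.validate()
    rng = _rng(config, "expression")
    em = config.expr_model
    out = {}
    for tid in triplets["triplet_id"]:
        g_eff = rng.normal(0.0, em.sigma_G, size=3)
        t_eff = rng.normal(0.0, em.sigma_T, size=4)
        if em.interaction_mode == "none":
            inter = np.zeros((3, 4))
        elif em.interaction_mode == "multiplicative":
            inter = em.sigma_GT * np.outer(g_eff, t_eff)
        else:  # free
            inter = rng.normal(0.0, em.sigma_GT, size=(3, 4))
        eps = rng.normal(0.0, em.sigma_eps, size=(3, 4))
        y = em.mu + g_eff[:, None] + t_eff[None, :] + inter + eps
        y[0, :] += em.lf_shift_delta
        out[str(tid)] = np.clip(np.expm1(y), 0.0, None)
    return out


def expression_frame(triplets: pd.DataFrame, fpkm: dict) -> pd.DataFrame:
    """Flatten triplet FPKM tables to one row per gene copy."""
    rows = []
    cols = ["lf_gene", "mf1_gene", "mf2_gene"]
    for _, row in triplets.iterrows():
        mat = fpkm[str(row["triplet_id"])]
        for gi, col in enumerate(cols):
            rows.append((row[col], *mat[gi]))
    return pd.DataFrame(rows, columns=["gene_id", *TISSUES])


# ---------------------------------------------------------------------------
# FDR half-tetrad progeny
# ---------------------------------------------------------------------------

def expected_fdr_het_frequency(map_distance_morgans) -> np.ndarray:
    """Closed-form FDR heterozygosity at map distance x from the centromere.

    Under a four-strand bivalent with Poisson crossovers and no chromatid
    interference the second-division-segregation frequency is
    y(x) = (2/3)(1 - exp(-3x)) and an FDR gamete is heterozygous with
    probability h = 1 - y/2 = (2 + exp(-3x)) / 3, decaying from 1 at the
    centromere to 2/3 far away.
    """
    x = np.asarray(map_distance_morgans, dtype=float)
    return (2.0 + np.exp(-3.0 * x)) / 3.0


def _trace_token(token: int, crossovers: list[tuple[float, int, int]]) -> int:
    for _, i, j in crossovers:
        if token == i:
            token = j
        elif token == j:
            token = i
    return token


def simulate_fdr_progeny(
    config: SimulationConfig, chrom: str = "chr1"
) -> pd.DataFrame:
    """Marker x progeny heterozygosity states from FDR unreduced gametes.

    Four chromatids are tracked through a bivalent with crossovers at rate
    2 per Morgan (Haldane, no interference); each crossover joins one
    chromatid from each homolog, chosen uniformly.  The FDR gamete takes
    one chromatid from each homolog (sisters chosen uniformly), so both
    parental centromeres are recovered and a marker is heterozygous exactly
    when its two chromatids carry different parental alleles.
    """
    config.validate()
    rng = _rng(config, "meiosis")
    mei = config.meiosis
    L = mei.map_length_morgans
    clen = config.chrom_length_bp
    marker_pos = np.linspace(1, clen, mei.n_markers).round().astype(int)
    to_map = lambda bp: L * (bp - 1) / max(clen - 1, 1)
    marker_map = to_map(marker_pos)
    cen_map = to_map(max(mei.resolved_centromere(clen), 1))

    states = np.empty((mei.n_markers, mei.n_progeny), dtype=object)
    for p in range(mei.n_progeny):
        n_co = rng.poisson(2.0 * L)
        xo_pos = np.sort(rng.uniform(0.0, L, size=n_co))
        xo_i = rng.integers(0, 2, size=n_co)        # chromatid of homolog 1
        xo_j = rng.integers(2, 4, size=n_co)        # chromatid of homolog 2
        s1 = int(rng.integers(0, 2))
        s2 = int(rng.integers(2, 4))
        for mi, x in enumerate(marker_map):
            lo, hi = min(cen_map, x), max(cen_map, x)
            # crossover positions are continuous, so boundary ties have
            # probability zero and the open interval suffices
            sel = [
                (abs(xp - cen_map), int(i), int(j))
                for xp, i, j in zip(xo_pos, xo_i, xo_j)
                if lo < xp < hi
            ]
            sel.sort()
            t1 = _trace_token(s1, sel)
            t2 = _trace_token(s2, sel)
            a1 = 0 if t1 < 2 else 1
            a2 = 0 if t2 < 2 else 1
            if a1 != a2:
                states[mi, p] = "het"
            else:
                states[mi, p] = "homA" if a1 == 0 else "homB"
        if mei.missing_rate > 0:
            miss = rng.random(mei.n_markers) < mei.missing_rate
            states[miss, p] = None
    meta = pd.DataFrame({
        "marker": [f"m{i + 1:04d}" for i in range(mei.n_markers)],
        "chrom": chrom,
        "pos": marker_pos,
    })
    prog = pd.DataFrame(
        states, columns=[f"progeny_{p + 1}" for p in range(mei.n_progeny)]
    )
    return pd.concat([meta, prog], axis=1)
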