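"""Readers and writers for the package's on-disk formats.

All tables are UTF-8, tab-separated, with a header row and ``.`` for missing
values; coordinates are 1-based inclusive (GFF3 convention) everywhere.
Stage outputs carry a provenance comment header (tool version, seed, config
hash) so a result file is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

METH_COLUMNS = ["chrom", "pos", "strand", "context", "ratio", "eff_CT_count", "C_count"]
HIT_COLUMNS = ["qseqid", "sseqid", "bitscore", "evalue"]
TRIPLET_COLUMNS = ["triplet_id", "lf_gene", "mf1_gene", "mf2_gene"]

PROMOTER_BP = 2000
DOWNSTREAM_BP = 2000


def provenance_header(seed=None, config=None, **extra) -> str:
    """Comment block recording tool version, seed and a config digest."""
    fields = {"tool": f"triplome {__version__}"}
    if seed is not None:
        fields["seed"] = seed
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        fields["config_sha1"] = hashlib.sha1(blob).hexdigest()[:12]
    fields.update(extra)
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def write_tsv(df: pd.DataFrame, path, seed=None, config=None, **extra) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config, **extra))
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def _read_tsv(path, required=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."])
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def read_methylation_tsv(path) -> pd.DataFrame:
    """Per-cytosine count table (methratio-like dialect).

    Columns: chrom, pos, strand, context, ratio, eff_CT_count (total reads n),
    C_count (methylated reads k).
    """
    df = _read_tsv(path, required=METH_COLUMNS)
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: invalid strand values {df.loc[bad, 'strand'].unique()}")
    bad = ~df["context"].isin(["CG", "CHG", "CHH"])
    if bad.any():
        raise ValueError(f"{path}: invalid contexts {df.loc[bad, 'context'].unique()}")
    if (df["C_count"] > df["eff_CT_count"]).any():
        raise ValueError(f"{path}: methylated count exceeds total count")
    return df


def read_expression_tsv(path, tissues=("leaf", "root", "flower", "pod")) -> pd.DataFrame:
    df = _read_tsv(path, required=["gene_id", *tissues])
    if (df[list(tissues)] < 0).any().any():
        raise ValueError(f"{path}: negative FPKM values")
    return df


def read_triplet_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, required=TRIPLET_COLUMNS)


def read_hits_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path, required=HIT_COLUMNS)
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative E-values")
    return df


def read_genotype_tsv(path) -> pd.DataFrame:
    """Marker x progeny matrix: marker, chrom, pos, then one column/progeny."""
    df = _read_tsv(path, required=["marker", "chrom", "pos"])
    states = df.iloc[:, 3:]
    valid = states.isin(["het", "homA", "homB"]) | states.isna()
    if not valid.all().all():
        raise ValueError(f"{path}: invalid genotype states")
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    return df


def read_syntelog_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, required=["ancestral_gene", "LF", "MF1", "MF2"])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict, path) -> None:
    """Write {name: sequence-string} at 60 columns."""
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# Gene models / GFF3
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene with its primary mRNA decomposed into parts.

    ``parts`` maps part name -> list of (start, end) 1-based inclusive
    intervals.  Promoter/downstream flanks and introns are derived, not
    stored in the GFF3.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    parts: dict = field(default_factory=dict)
    category: str = "unassigned"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def derive_flanks_and_introns(gene: GeneModel, chrom_length: int | None = None,
                              promoter_bp: int = PROMOTER_BP,
                              downstream_bp: int = DOWNSTREAM_BP) -> None:
    """Attach promoter/downstream windows and infer introns from exon gaps."""
    exons = sorted(gene.parts.get("exon", []))
    introns = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 > e1 + 1:
            introns.append((e1 + 1, s2 - 1))
    gene.parts["intron"] = introns
    if gene.strand == "+":
        prom = (gene.start - promoter_bp, gene.start - 1)
        down = (gene.end + 1, gene.end + downstream_bp)
    else:
        prom = (gene.end + 1, gene.end + promoter_bp)
        down = (gene.start - downstream_bp, gene.start - 1)
    clip = lambda iv: (max(iv[0], 1),
                       min(iv[1], chrom_length) if chrom_length else iv[1])
    for name, iv in (("promoter", prom), ("downstream", down)):
        iv = clip(iv)
        gene.parts[name] = [iv] if iv[0] <= iv[1] else []


def write_gff3(genes: list[GeneModel], path, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(provenance_header(seed=seed, config=config))
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\ttriplome\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\ttriplome\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for part in ("five_prime_UTR", "exon", "three_prime_UTR"):
                for i, (s, e) in enumerate(sorted(g.parts.get(part, [])), 1):
                    fh.write(
                        f"{g.chrom}\ttriplome\t{part}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={mrna}.{part}.{i};Parent={mrna}\n"
                    )


def read_gff3(path, chrom_lengths: dict | None = None) -> list[GeneModel]:
    """Parse gene models; derive introns and promoter/downstream flanks.

    One primary mRNA per gene is used (longest summed exon length, ties
    broken by mRNA id).  Exons outside their gene span or unknown strands
    are hard errors.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for grec in db.features_of_type("gene"):
        if grec.strand not in ("+", "-"):
            raise ValueError(f"{path}: gene {grec.id} has unknown strand")
        if chrom_lengths is not None:
            clen = chrom_lengths.get(grec.seqid)
            if clen is None or grec.start < 1 or grec.end > clen:
                raise ValueError(
                    f"{path}: gene {grec.id} outside chromosome bounds"
                )
        mrnas = list(db.children(grec, featuretype="mRNA"))
        best, best_key = None, None
        for m in mrnas:
            exlen = sum(
                c.end - c.start + 1 for c in db.children(m, featuretype="exon")
            )
            key = (-exlen, m.id)
            if best_key is None or key < best_key:
                best, best_key = m, key
        gene = GeneModel(
            gene_id=grec.id, chrom=grec.seqid, strand=grec.strand,
            start=grec.start, end=grec.end,
        )
        if best is not None:
            for part in ("exon", "five_prime_UTR", "three_prime_UTR"):
                ivs = []
                for c in db.children(best, featuretype=part):
                    if c.start < grec.start or c.end > grec.end:
                        raise ValueError(
                            f"{path}: {part} of {grec.id} outside gene span"
                        )
                    ivs.append((c.start, c.end))
                gene.parts[part] = sorted(ivs)
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        derive_flanks_and_introns(gene, chrom_length=clen)
        genes.append(gene)
    return genes


def features_frame(genes: list[GeneModel]) -> pd.DataFrame:
    """Flatten gene models to one row per part interval."""
    rows = []
    for g in genes:
        for part, ivs in g.parts.items():
            for s, e in ivs:
                rows.append((g.gene_id, g.chrom, g.strand, part, s, e, g.category))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "strand", "part", "start", "end", "category"],
    )


# ---------------------------------------------------------------------------
# Track output
# ---------------------------------------------------------------------------

def write_bedgraph(track: pd.DataFrame, path, name="triplome_track") -> None:
    """bedGraph is 0-based half-open; converted here at the boundary."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for _, row in track.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"{row['value']}\n"
            )
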