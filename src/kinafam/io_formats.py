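"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Bio.SeqIO, GFF3 through gffutils; the kiwifruit MAPK
roster table ships as a packaged TSV fixture. Coordinates are stored GFF3
1-based inclusive throughout; conversion to 0-based half-open happens only
inside slicing helpers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .phylotree import Node

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass
class SeqRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.sequence:
            raise ValidationError(f"{self.id}: empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One annotated gene: 1-based inclusive intervals, ascending order."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        for name, ivs in (("exon", self.exons), ("CDS", self.cds_segments)):
            prev_end = 0
            for start, end in ivs:
                if end < start:
                    raise ValidationError(
                        f"{self.gene_id}: {name} end {end} < start {start}")
                if start <= prev_end:
                    raise ValidationError(
                        f"{self.gene_id}: {name} intervals overlap or unsorted")
                prev_end = end
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exons")
        if self.cds_segments and self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class FamilyTableRow:
    name: str
    gene_id: str
    chromosome: str
    aa_length: int
    cds_length_bp: int
    mw_kda: float
    pi: float
    exon_count: int
    tloop: str
    group: str | None = None
    location: str | None = None

    def __post_init__(self):
        if self.tloop not in ("TEY", "TDY"):
            raise ValidationError(f"{self.name}: T-loop must be TEY or TDY")
        if self.exon_count < 1:
            raise ValidationError(f"{self.name}: exon count < 1")
        if self.aa_length != self.cds_length_bp // 3 - 1:
            raise ValidationError(
                f"{self.name}: aa length {self.aa_length} != "
                f"floor({self.cds_length_bp}/3) - 1")


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[SeqRecord]:
    text = Path(path).read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>'")
            break
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        desc = rec.description[len(rec.id):].strip()
        records.append(SeqRecord(id=rec.id, sequence=str(rec.seq),
                                 description=desc))
    return records


def write_fasta(records: list[SeqRecord], path, width: int = 70) -> None:
    bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
           for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ----------------------------------------------------------------- GFF3

def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    genes: list[GeneModel] = []
    gene_ids = set()
    for gene in db.features_of_type("gene", order_by="start"):
        gene_ids.add(gene.id)
        exons, cds = [], []
        for child in db.children(gene.id):
            if child.end < child.start:
                raise ParseError(
                    f"{path}: feature with end < start in gene {gene.id}")
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype == "CDS":
                cds.append((child.start, child.end))
        genes.append(GeneModel(
            gene_id=gene.id, chromosome=gene.seqid, strand=gene.strand,
            exons=sorted(exons), cds_segments=sorted(cds)))
    # orphan CDS check: every CDS must reach a gene through its Parent chain
    for feat in db.features_of_type("CDS"):
        ancestors = {a.id for a in db.parents(feat.id)}
        if not ancestors & gene_ids:
            raise ParseError(f"{path}: CDS {feat.id} has no parent gene")
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            fh.write(f"{g.chromosome}\tkinafam\tgene\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chromosome}\tkinafam\tmRNA\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.chromosome}\tkinafam\texon\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tParent={mrna}\n")
            for s, e in g.cds_segments:
                fh.write(f"{g.chromosome}\tkinafam\tCDS\t{s}\t{e}\t.\t"
                         f"{g.strand}\t0\tParent={mrna}\n")


# ----------------------------------------------------- family table TSV

_TABLE_COLUMNS = ["name", "gene_id", "chromosome", "aa_length",
                  "cds_length_bp", "mw_kda", "pi", "exon_count", "tloop",
                  "location"]


def read_family_table(path) -> list[FamilyTableRow]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    rows = []
    for _, r in df.iterrows():
        try:
            rows.append(FamilyTableRow(
                name=r["name"], gene_id=r["gene_id"],
                chromosome=str(r["chromosome"]),
                aa_length=int(r["aa_length"]),
                cds_length_bp=int(r["cds_length_bp"]),
                mw_kda=float(r["mw_kda"]), pi=float(r["pi"]),
                exon_count=int(r["exon_count"]), tloop=r["tloop"],
                group=r.get("group"), location=r.get("location")))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {r['name']}: {exc}") from exc
    return rows


def write_family_table(rows: list[FamilyTableRow], path) -> None:
    df = pd.DataFrame([{
        "name": r.name, "gene_id": r.gene_id, "chromosome": r.chromosome,
        "aa_length": r.aa_length, "cds_length_bp": r.cds_length_bp,
        "mw_kda": r.mw_kda, "pi": r.pi, "exon_count": r.exon_count,
        "tloop": r.tloop, "group": r.group or "",
        "location": r.location or ""} for r in rows])
    df.to_csv(path, sep="\t", index=False)


def packaged_family_table() -> list[FamilyTableRow]:
    """The kiwifruit MAPK roster shipped with the package (18 genes)."""
    with resources.as_file(resources.files("kinafam.data")
                           / "family_table.tsv") as p:
        return read_family_table(p)


def packaged_subfamily_assignments() -> dict[str, str]:
    """Published subfamily (A-E) per kiwifruit MAPK gene name."""
    with resources.as_file(resources.files("kinafam.data")
                           / "subfamily_assignments.tsv") as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return dict(zip(df["name"], df["group"]))


# ---------------------------------------------------------------- Newick

def write_newick(tree: Node) -> str:
    names = tree.leaf_names()
    if len(names) != len(set(names)):
        raise ValidationError("duplicate leaf labels in tree")

    def fmt(node: Node) -> str:
        if node.is_leaf:
            label = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            sup = ("" if node.support is None
                   else format(node.support, "g"))
            label = f"({inner}){sup}"
        if node.length is not None:
            label += f":{_fmt_len(node.length)}"
        return label

    return fmt(tree) + ";"


def _fmt_len(x: float) -> str:
    s = repr(round(float(x), 10))
    return s if "." in s or "e" in s else s + ".0"


def parse_newick(text: str) -> Node:
    """Minimal Newick parser: supports as internal-node labels."""
    text = text.strip()
    if not text.endswith(";"):
        raise ParseError("newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise ParseError("unbalanced parentheses in newick")
            pos += 1
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                node.support = float(label)
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ParseError(f"trailing characters in newick at {pos}")
    return root
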