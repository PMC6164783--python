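"""Promoter extraction and IUPAC cis-regulatory element scanning.

Promoters are the 1500 bp immediately upstream of the translation start
(ATG); elements are IUPAC degenerate patterns scanned on both strands with
overlapping matches counted, as PLACE-style scans do.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .gene_annotation import reverse_complement
from .io_formats import GeneModel, SeqRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class CisElement:
    name: str
    iupac_pattern: str
    category: str = "other"

    def __post_init__(self):
        if not self.iupac_pattern:
            raise ValueError(f"{self.name}: empty pattern")
        bad = set(self.iupac_pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC letters {bad}")
        self.iupac_pattern = self.iupac_pattern.upper()

    @property
    def regex(self) -> re.Pattern:
        return re.compile("(?=(" + "".join(
            IUPAC[c] for c in self.iupac_pattern) + "))")

    @property
    def revcomp_pattern(self) -> str:
        return self.iupac_pattern.translate(IUPAC_COMPLEMENT)[::-1]


def read_element_table(path) -> list[CisElement]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [CisElement(name=r["name"], iupac_pattern=r["pattern"],
                       category=r.get("category", "other"))
            for _, r in df.iterrows()]


def packaged_element_table() -> list[CisElement]:
    with resources.as_file(resources.files("kinafam.data")
                           / "cis_elements.tsv") as p:
        return read_element_table(p)


def extract_upstream(gene: GeneModel, genome: dict[str, str],
                     length: int = 1500) -> SeqRecord:
    """The `length` bases immediately 5' of the gene's ATG.

    Plus strand: bases [atg-length, atg-1] in genome coordinates. Minus
    strand: the bases genomically 3' of the CDS end, reverse-complemented.
    Clipped with a warning at contig edges.
    """
    if not gene.cds_segments:
        raise ValueError(f"{gene.gene_id}: gene has no CDS")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        atg = gene.cds_segments[0][0]  # 1-based position of the A of ATG
        start = atg - length  # 1-based
        if start < 1:
            warnings.warn(f"{gene.gene_id}: promoter clipped at contig start")
            start = 1
        seq = chrom[start - 1:atg - 1]
    else:
        cds_end = gene.cds_segments[-1][1]
        end = cds_end + length
        if end > len(chrom):
            warnings.warn(f"{gene.gene_id}: promoter clipped at contig end")
            end = len(chrom)
        seq = reverse_complement(chrom[cds_end:end])
    return SeqRecord(id=gene.gene_id, sequence=seq,
                     description=f"{length} bp upstream promoter")


def iupac_scan(seq: str, element: CisElement,
               both_strands: bool = True) -> list[tuple[int, str]]:
    """All (overlapping) matches as (1-based plus-strand offset, strand)."""
    seq = seq.upper()
    hits = [(m.start() + 1, "+") for m in element.regex.finditer(seq)]
    if both_strands:
        rc = CisElement(name=element.name,
                        iupac_pattern=element.revcomp_pattern,
                        category=element.category)
        hits += [(m.start() + 1, "-") for m in rc.regex.finditer(seq)]
    return sorted(hits)


def count_elements(promoters: list[SeqRecord], elements: list[CisElement],
                   both_strands: bool = True):
    """(gene x element count DataFrame, gene x category totals DataFrame)."""
    genes = [p.id for p in promoters]
    counts = pd.DataFrame(0, index=genes,
                          columns=[e.name for e in elements], dtype=int)
    for p in promoters:
        for e in elements:
            counts.loc[p.id, e.name] = len(
                iupac_scan(p.sequence, e, both_strands))
    categories = sorted({e.category for e in elements})
    totals = pd.DataFrame(0, index=genes, columns=categories, dtype=int)
    for e in elements:
        totals[e.category] += counts[e.name]
    return counts, totals
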