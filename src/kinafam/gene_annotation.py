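"""Gene-structure extraction, CDS assembly/translation, protein properties.

Molecular weights are Expasy-style average masses; isoelectric points come
from the Bjellqvist pKa set via bisection on the net-charge curve, matching
the compute pI/MW convention the roster table was built with.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight as _bio_mw

from .io_formats import GeneModel, SeqRecord, ValidationError


@dataclass
class ProteinProperties:
    length: int
    mw_da: float
    pi: float

    def __post_init__(self):
        if self.length < 1 or self.mw_da <= 0 or not 0 < self.pi < 14:
            raise ValidationError("implausible protein properties")


COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def extract_cds(gene: GeneModel, genome: dict[str, str]) -> str:
    """Spliced CDS in transcript orientation (minus strand revcomped)."""
    if gene.chromosome not in genome:
        raise ValueError(f"{gene.gene_id}: chromosome {gene.chromosome} "
                         "absent from genome")
    chrom = genome[gene.chromosome]
    if not gene.cds_segments:
        raise ValueError(f"{gene.gene_id}: no CDS segments")
    parts = []
    for start, end in gene.cds_segments:  # 1-based inclusive
        if start < 1 or end > len(chrom):
            raise ValueError(f"{gene.gene_id}: CDS segment {start}-{end} "
                             "outside chromosome bounds")
        parts.append(chrom[start - 1:end])
    cds = "".join(parts)
    if gene.strand == "-":
        cds = reverse_complement(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length {len(cds)} "
                         "not divisible by 3")
    return cds


def translate(cds: str, ambiguous: str = "error") -> str:
    """Translate a CDS with the standard code; the stop is not counted.

    An internal stop raises; an ambiguous codon (containing N) raises by
    default or emits 'X' when ambiguous='X'.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    aa = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if "N" in codon:
            if ambiguous == "X":
                aa.append("X")
                continue
            raise ValueError(f"ambiguous codon {codon} at position {i + 1}")
        res = str(Seq(codon).translate())
        if res == "*":
            if i + 3 == len(cds):
                break
            raise ValueError(f"internal stop codon at position {i + 1}")
        aa.append(res)
    return "".join(aa)


def molecular_weight(protein: str) -> float:
    """Average-mass molecular weight in daltons."""
    bad = set(protein) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"nonstandard residues: {sorted(bad)}")
    return float(_bio_mw(protein, seq_type="protein", monoisotopic=False))


# Bjellqvist pKa values (Expasy compute pI/MW set)
PKA_NTERM = 9.094  # generic alpha-amino (internal default)
PKA_CTERM = 3.55
PKA_SIDE_ACID = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_SIDE_BASE = {"H": 5.98, "K": 10.0, "R": 12.0}
# N-terminal pKa depends on the first residue (Bjellqvist)
PKA_NTERM_BY_RES = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                    "V": 7.44, "E": 7.7}


def net_charge(protein: str, ph: float) -> float:
    """Net charge at a given pH under the Bjellqvist model."""
    comp = Counter(protein)
    pos = 10 ** -ph / (10 ** -PKA_NTERM_BY_RES.get(protein[0], PKA_NTERM)
                       + 10 ** -ph)
    for res, pka in PKA_SIDE_BASE.items():
        pos += comp[res] * 10 ** -ph / (10 ** -pka + 10 ** -ph)
    neg = 10 ** -PKA_CTERM / (10 ** -PKA_CTERM + 10 ** -ph)
    for res, pka in PKA_SIDE_ACID.items():
        neg += comp[res] * 10 ** -pka / (10 ** -pka + 10 ** -ph)
    return pos - neg


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which net charge is zero, by bisection on [0, 14]."""
    bad = set(protein) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise ValueError(f"nonstandard residues: {sorted(bad)}")
    lo, hi = 0.0, 14.0
    while hi - lo > tol / 10:
        mid = (lo + hi) / 2
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def protein_properties(protein: str) -> ProteinProperties:
    return ProteinProperties(length=len(protein),
                             mw_da=molecular_weight(protein),
                             pi=isoelectric_point(protein))


# -------------------------------------------------------------- summaries

def exon_summary(genes: list[GeneModel]):
    """Per-gene exon counts plus (min, max) over the set."""
    counts = {g.gene_id: g.exon_count for g in genes}
    values = list(counts.values())
    return counts, (min(values), max(values))


def chromosome_distribution(rows) -> dict[str, int]:
    """Gene counts per chromosome label ('Un' is a single label)."""
    dist: dict[str, int] = {}
    for r in rows:
        chrom = r.chromosome if hasattr(r, "chromosome") else r
        dist[chrom] = dist.get(chrom, 0) + 1
    return dist


def gene_structure_table(genes: list[GeneModel]):
    """Exon/intron tiling per gene for structure plots (BED-like rows).

    Features tile the gene span exactly: alternating exons and introns with
    no gaps or overlaps, coordinates 1-based inclusive.
    """
    rows = []
    for g in genes:
        span_start, span_end = g.span
        prev_end = None
        for s, e in g.exons:
            if prev_end is not None and s > prev_end + 1:
                rows.append({"gene_id": g.gene_id, "feature": "intron",
                             "start": prev_end + 1, "end": s - 1,
                             "strand": g.strand})
            rows.append({"gene_id": g.gene_id, "feature": "exon",
                         "start": s, "end": e, "strand": g.strand})
            prev_end = e
        assert rows[-1]["end"] == span_end and g.exons[0][0] == span_start
    return rows
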