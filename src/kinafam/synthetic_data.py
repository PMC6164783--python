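"""Toy genome, promoter and qPCR-table generator with known ground truth.

The generator emulates the inputs of a genome-wide MAPK family survey:
multi-exon kinase genes whose spliced CDS translates to a protein carrying
the conserved subdomain anchors, a TEY or TDY activation loop and a CD
docking motif, with group-typical exon counts; decoy genes that must be
rejected; promoters with planted cis-elements on an element-free background;
and Ct tables with planted fold changes plus Gaussian cycle noise.

Sequence realism is deliberately minimal (star-like divergence within each
subfamily, uniform codon choice); what is controlled exactly is the ground
truth every downstream stage is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import GeneModel, SeqRecord
from .kinase_scan import find_signature
from .promoter_scan import IUPAC, CisElement, iupac_scan

GROUPS = "ABCDE"

# Residues that cannot form any anchor motif, T[DE]Y loop or CD motif, used
# for linkers, mutations and random decoys so planted signatures stay unique.
NEUTRAL_AA = "ACFHILMNPQRSTVW"

ANCHOR_GXGXXG = "GEGSYG"
ANCHOR_VAIK = "VAIK"
ANCHOR_HRD = "HRDLKP"
ANCHOR_DFG = "DFG"
ANCHOR_APE = "APE"
ANCHOR_CD = "LHDKNDEPNC"

DEFAULT_TREATMENT_TIMEPOINTS = {
    "ABA": (0, 4, 12, 48), "ACC": (0, 4, 12, 48), "SA": (0, 4, 12, 48),
    "JA": (0, 4, 12, 48), "cold": (0, 4, 12, 48), "heat": (0, 2, 4, 10),
    "salt": (0, 4, 12, 48), "Psa": (24, 48, 96),
}
PAIRED_CONTROL_TREATMENTS = ("Psa",)  # mock control sampled per timepoint


@dataclass
class SynthConfig:
    seed: int = 0
    n_members_per_group: dict = field(default_factory=lambda: {
        "A": 4, "B": 5, "C": 3, "D": 3, "E": 3})
    n_decoys: int = 10
    exon_count_ranges: dict = field(default_factory=lambda: {
        "A": (5, 7), "B": (6, 8), "C": (2, 3), "D": (9, 11), "E": (16, 29)})
    promoter_len: int = 1500
    element_plant_counts: dict = field(default_factory=lambda: {
        "as-1/TGACG": 2, "W-box": 1, "HSE": 1})
    ct_noise_sd: float = 0.2
    fold_changes: dict | None = None  # (gene, treatment, timepoint) -> fold
    tdy_e_member: bool = True  # one group-E member with a TDY loop
    n_references_per_group: int = 2
    within_group_mutation_rate: float = 0.03
    replicates: int = 3
    treatments: dict = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_TIMEPOINTS))

    def __post_init__(self):
        if any(v < 0 for v in self.n_members_per_group.values()):
            raise ValueError("group sizes must be nonnegative")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be nonnegative")
        for g, (lo, hi) in self.exon_count_ranges.items():
            if not 1 <= lo <= hi <= 64:
                raise ValueError(f"group {g}: empty or invalid exon range")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be nonnegative")


@dataclass
class TruthTable:
    members: pd.DataFrame  # gene_id, group, tloop, exon_count, protein
    decoys: dict  # gene_id -> reason it must be rejected
    element_counts: pd.DataFrame | None = None
    fold_changes: dict | None = None


@dataclass
class ToyGenome:
    genome: dict  # chromosome -> sequence
    annotation: list  # GeneModel
    proteins: list  # SeqRecord (planted + decoys)
    references: list  # SeqRecord, reference kinases with known groups
    ref_groups: dict  # reference id -> group
    truth: TruthTable
    config: SynthConfig

    @property
    def genome_records(self) -> list:
        return [SeqRecord(id=c, sequence=s) for c, s in self.genome.items()]


# ------------------------------------------------------- protein layer

def _linker(rng, lo=10, hi=40) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(NEUTRAL_AA), size=n))


def _kinase_consensus(rng, tloop: str, tail_len: int) -> str:
    parts = ["M", _linker(rng, 20, 50), ANCHOR_GXGXXG, _linker(rng),
             ANCHOR_VAIK, _linker(rng), ANCHOR_HRD, _linker(rng),
             ANCHOR_DFG, _linker(rng, 5, 12), tloop, _linker(rng, 5, 12),
             ANCHOR_APE, _linker(rng), ANCHOR_CD,
             _linker(rng, tail_len, tail_len + 40)]
    return "".join(parts)


def _protected_positions(protein: str) -> set[int]:
    """0-based positions inside anchor motifs, the T-loop, or the CD motif."""
    sig = find_signature(protein)
    lengths = {"GxGxxG": len(ANCHOR_GXGXXG), "VAIK": len(ANCHOR_VAIK),
               "HRD": len(ANCHOR_HRD), "DFG": len(ANCHOR_DFG),
               "APE": len(ANCHOR_APE)}
    protected = set()
    for name, pos in sig.anchor_positions.items():
        protected.update(range(pos - 1, pos - 1 + lengths[name]))
    if sig.tloop_pos:
        protected.update(range(sig.tloop_pos - 1, sig.tloop_pos + 2))
    if sig.cd_span:
        protected.update(range(sig.cd_span[0] - 1, sig.cd_span[1]))
    return protected


def _mutate(protein: str, rng, rate: float,
            protected: set[int] | None = None) -> str:
    """Point substitutions at neutral, non-anchor positions only."""
    out = list(protein)
    neutral = set(NEUTRAL_AA)
    protected = protected or set()
    for i in range(1, len(out)):  # keep the initiator M
        if i in protected or out[i] not in neutral:
            continue
        if rng.random() < rate:
            out[i] = NEUTRAL_AA[int(rng.integers(len(NEUTRAL_AA)))]
    return "".join(out)


def _random_decoy_protein(rng, length: int) -> str:
    return "M" + "".join(rng.choice(list(NEUTRAL_AA), size=length - 1))


def _excised_tloop_protein(consensus: str, rng) -> str:
    sig = find_signature(consensus)
    assert sig.tloop_pos is not None
    i = sig.tloop_pos - 1
    repl = "".join(rng.choice(list(NEUTRAL_AA), size=3))
    return consensus[:i] + repl + consensus[i + 3:]


# ----------------------------------------------------------- DNA layer

_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)


def _reverse_translate(protein: str, rng) -> str:
    cds = ["ATG"]  # the initiator M
    for aa in protein[1:]:
        options = _CODONS[aa]
        cds.append(options[int(rng.integers(len(options)))])
    cds.append("TAA")
    return "".join(cds)


def _random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _element_free(seq: str, elements: list[CisElement], rng,
                  max_rounds: int = 2000) -> str:
    """Scrub a background sequence of all element matches (both strands)."""
    s = list(seq)
    for _ in range(max_rounds):
        hits = []
        text = "".join(s)
        for e in elements:
            for off, _strand in iupac_scan(text, e):
                hits.append((off - 1, len(e.iupac_pattern)))
        if not hits:
            return text
        for off, width in hits:
            j = off + int(rng.integers(width))
            s[j] = "ACGT"[int(rng.integers(4))]
    raise RuntimeError("could not scrub promoter background of elements")


def _split_cds(length: int, n_exons: int, rng) -> list[int]:
    """Piece lengths >= 3 summing to `length`."""
    if length < 3 * n_exons:
        raise ValueError("CDS too short for requested exon count")
    extra = rng.multinomial(length - 3 * n_exons,
                            np.ones(n_exons) / n_exons)
    return [3 + int(e) for e in extra]


def _build_cassette(protein: str, n_exons: int, promoter: str, rng):
    """(sequence, exon intervals 1-based rel) with the ATG right after
    the promoter."""
    cds = _reverse_translate(protein, rng)
    pieces = _split_cds(len(cds), n_exons, rng)
    seq = [promoter]
    pos = len(promoter)
    exons = []
    cursor = 0
    for k, plen in enumerate(pieces):
        if k > 0:
            ilen = int(rng.integers(60, 401))
            intron = "GT" + _random_dna(rng, ilen - 4) + "AG"
            seq.append(intron)
            pos += ilen
        seq.append(cds[cursor:cursor + plen])
        exons.append((pos + 1, pos + plen))
        pos += plen
        cursor += plen
    seq.append(_random_dna(rng, 100))
    return "".join(seq), exons


# ------------------------------------------------------------ main ops

def generate_toy_genome(config: SynthConfig | None = None,
                        elements: list[CisElement] | None = None
                        ) -> ToyGenome:
    """Deterministic toy genome + annotation + proteins + ground truth.

    Promoter backgrounds are scrubbed of every pattern in `elements` (both
    strands) so that planted occurrences are exactly recoverable.
    """
    config = config or SynthConfig()
    if elements is None:
        from .promoter_scan import packaged_element_table
        elements = packaged_element_table()
    rng = np.random.default_rng([config.seed, 1])

    # group consensus proteins and members
    members = []  # (gene_id, group, tloop, protein)
    consensus_by_group = {}
    for g in GROUPS:
        n = config.n_members_per_group.get(g, 0)
        # C-terminal extension lengths give group-typical protein sizes
        # (TDY-group and E-group kinases are the long ones)
        tail = {"A": 230, "B": 250, "C": 220, "D": 420, "E": 300}[g]
        base_tloop = "TDY" if g == "D" else "TEY"
        consensus_by_group[g] = _kinase_consensus(rng, base_tloop, tail)
        protected = _protected_positions(consensus_by_group[g])
        for k in range(n):
            tloop = base_tloop
            protein = _mutate(consensus_by_group[g], rng,
                              config.within_group_mutation_rate, protected)
            if g == "E" and k == n - 1 and config.tdy_e_member:
                # one group-E member carries a TDY loop (AcMAPK18-like)
                sig = find_signature(protein)
                i = sig.tloop_pos - 1
                protein = protein[:i] + "TDY" + protein[i + 3:]
                tloop = "TDY"
            members.append((f"synmapk{g}{k + 1}", g, tloop, protein))

    # decoys: random non-kinases + kinase-like with the T-X-Y excised
    decoys = {}
    decoy_seqs = []
    n_excised = min(config.n_decoys // 3, len(consensus_by_group))
    for k in range(config.n_decoys):
        gid = f"decoy{k + 1:02d}"
        if k < n_excised:
            g = GROUPS[k % len(GROUPS)]
            seq = _excised_tloop_protein(consensus_by_group[g], rng)
            decoys[gid] = "kinase-like but T-X-Y activation loop excised"
        else:
            seq = _random_decoy_protein(rng, int(rng.integers(280, 420)))
            decoys[gid] = "random non-kinase protein"
        decoy_seqs.append((gid, seq))

    # references per group (for search queries and the phylogeny panel)
    references, ref_groups = [], {}
    for g in GROUPS:
        for k in range(config.n_references_per_group):
            rid = f"REF_{g}{k + 1}"
            prot = _mutate(consensus_by_group[g], rng,
                           config.within_group_mutation_rate,
                           _protected_positions(consensus_by_group[g]))
            references.append(SeqRecord(id=rid, sequence=prot,
                                        description=f"group {g} reference"))
            ref_groups[rid] = g

    # genome assembly
    chromosomes = [f"chr{i}" for i in range(1, 11)] + ["Un"]
    genome: dict[str, list[str]] = {c: [] for c in chromosomes}
    offsets = {c: 0 for c in chromosomes}
    annotation: list[GeneModel] = []
    truth_rows = []

    all_genes = [(gid, g, tloop, prot) for gid, g, tloop, prot in members]
    all_genes += [(gid, None, None, prot) for gid, prot in decoy_seqs]
    for idx, (gid, g, tloop, prot) in enumerate(all_genes):
        chrom = chromosomes[idx % len(chromosomes)]
        strand = "+" if rng.random() < 0.5 else "-"
        if g is not None:
            lo, hi = config.exon_count_ranges[g]
            n_exons = int(rng.integers(lo, hi + 1))
        else:
            n_exons = int(rng.integers(1, 4))
        promoter = _element_free(_random_dna(rng, config.promoter_len),
                                 elements, rng)
        cassette, exons_rel = _build_cassette(prot, n_exons, promoter, rng)
        spacer = _random_dna(rng, 100)
        off = offsets[chrom] + len(spacer)
        L = len(cassette)
        if strand == "+":
            placed = cassette
            exons = [(off + s, off + e) for s, e in exons_rel]
        else:
            placed = "".join(
                {"A": "T", "C": "G", "G": "C", "T": "A"}[b]
                for b in reversed(cassette))
            exons = sorted((off + L - e + 1, off + L - s + 1)
                           for s, e in exons_rel)
        genome[chrom].append(spacer + placed)
        offsets[chrom] = off + L
        annotation.append(GeneModel(gene_id=gid, chromosome=chrom,
                                    strand=strand, exons=exons,
                                    cds_segments=list(exons)))
        if g is not None:
            truth_rows.append({"gene_id": gid, "group": g, "tloop": tloop,
                               "exon_count": n_exons, "protein": prot})

    proteins = [SeqRecord(id=gid, sequence=prot)
                for gid, _g, _t, prot in members]
    proteins += [SeqRecord(id=gid, sequence=prot)
                 for gid, prot in decoy_seqs]
    truth = TruthTable(members=pd.DataFrame(truth_rows), decoys=decoys)
    annotation.sort(key=lambda g: g.gene_id)
    return ToyGenome(genome={c: "".join(parts) for c, parts in genome.items()
                             if parts},
                     annotation=annotation, proteins=proteins,
                     references=references, ref_groups=ref_groups,
                     truth=truth, config=config)


def _realize_iupac(pattern: str, rng) -> str:
    out = []
    for c in pattern:
        choices = IUPAC[c].strip("[]")
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def plant_promoter_elements(toy: ToyGenome,
                            elements: list[CisElement] | None = None,
                            max_tries: int = 200):
    """Plant cis-elements into each family gene's promoter; update genome.

    Returns (promoters, truth_counts). Planted counts are verified by
    re-scanning: offsets are re-drawn until the scan reproduces the planted
    counts exactly for every element in the table (no background collisions
    can occur because backgrounds were scrubbed at generation time).
    """
    if elements is None:
        from .promoter_scan import packaged_element_table
        elements = packaged_element_table()
    config = toy.config
    by_name = {e.name: e for e in elements}
    plant = {name: cnt for name, cnt in config.element_plant_counts.items()
             if cnt > 0}
    for name in plant:
        if name not in by_name:
            raise ValueError(f"unknown element {name}")
        if len(by_name[name].iupac_pattern) > config.promoter_len:
            raise ValueError(f"element {name} longer than promoter")
    rng = np.random.default_rng([config.seed, 2])
    family_ids = set(toy.truth.members["gene_id"])
    from .promoter_scan import extract_upstream
    promoters, count_rows = [], []
    genome = dict(toy.genome)
    for gene in toy.annotation:
        base = extract_upstream(gene, genome, config.promoter_len).sequence
        counts = {e.name: 0 for e in elements}
        if gene.gene_id in family_ids and plant:
            # a palindromic pattern (its own reverse complement) hits on
            # both strands, so one planted copy scans as two hits
            want = {e.name: plant.get(e.name, 0)
                    * (2 if e.revcomp_pattern == e.iupac_pattern else 1)
                    for e in elements}
            for attempt in range(max_tries):
                seq = _plant_once(base, plant, by_name, rng)
                if seq is None:
                    continue
                scanned = {e.name: len(iupac_scan(seq, e)) for e in elements}
                if scanned == want:
                    base, counts = seq, want
                    break
            else:
                raise RuntimeError(
                    f"{gene.gene_id}: could not plant elements cleanly")
            genome[gene.chromosome] = _write_promoter(
                genome[gene.chromosome], gene, base, config.promoter_len)
        promoters.append(SeqRecord(id=gene.gene_id, sequence=base,
                                   description="promoter"))
        count_rows.append({"gene_id": gene.gene_id, **counts})
    toy.genome = genome
    truth_counts = pd.DataFrame(count_rows).set_index("gene_id")
    toy.truth.element_counts = truth_counts
    return promoters, truth_counts


def _plant_once(base: str, plant: dict, by_name: dict, rng) -> str | None:
    seq = list(base)
    used: list[tuple[int, int]] = []
    for name in sorted(plant):
        e = by_name[name]
        w = len(e.iupac_pattern)
        for _ in range(plant[name]):
            for _try in range(50):
                off = int(rng.integers(0, len(seq) - w + 1))
                if all(off + w + 2 <= s or off >= s + l + 2
                       for s, l in used):
                    realized = _realize_iupac(e.iupac_pattern, rng)
                    seq[off:off + w] = realized
                    used.append((off, w))
                    break
            else:
                return None
    return "".join(seq)


def _write_promoter(chrom: str, gene: GeneModel, promoter: str,
                    length: int) -> str:
    if gene.strand == "+":
        atg = gene.cds_segments[0][0]
        start = atg - length  # 1-based
        return chrom[:start - 1] + promoter + chrom[atg - 1:]
    cds_end = gene.cds_segments[-1][1]
    rc = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[b]
                 for b in reversed(promoter))
    return chrom[:cds_end] + rc + chrom[cds_end + length:]


def simulate_ct_table(toy_or_config, genes: list[str] | None = None):
    """Long-format Ct table with planted fold changes.

    Ct_target(treated cell) = Ct_target(baseline) - log2(fold) + noise;
    the reference (actin-like) gene is constant up to the same noise.
    Returns (table, fold_truth) and stores the truth on the toy's TruthTable
    when a ToyGenome is given.
    """
    if isinstance(toy_or_config, ToyGenome):
        toy, config = toy_or_config, toy_or_config.config
        if genes is None:
            genes = list(toy.truth.members["gene_id"])
    else:
        toy, config = None, toy_or_config
        if genes is None:
            raise ValueError("gene list required without a ToyGenome")
    rng = np.random.default_rng([config.seed, 3])
    sd = config.ct_noise_sd
    ref_base = 18.0
    folds = dict(config.fold_changes or {})
    rows = []
    for gene in genes:
        target_base = float(20.0 + 6.0 * rng.random())
        for trt, timepoints in config.treatments.items():
            paired = trt in PAIRED_CONTROL_TREATMENTS
            for tp in timepoints:
                key = (gene, trt, tp)
                if key not in folds:
                    if tp == 0 and not paired:
                        folds[key] = 1.0
                    else:
                        folds[key] = float(2.0 ** rng.uniform(-3, 3))
                if folds[key] <= 0:
                    raise ValueError(f"fold must be positive at {key}")
                conditions = (("treated", folds[key]),) if not paired \
                    else (("treated", folds[key]), ("control", 1.0))
                for cond, fold in conditions:
                    for rep in range(1, config.replicates + 1):
                        ct_t = (target_base - np.log2(fold)
                                + rng.normal(0, sd))
                        ct_r = ref_base + rng.normal(0, sd)
                        rows.append({
                            "gene": gene, "treatment": trt,
                            "timepoint": tp, "replicate": rep,
                            "condition": cond,
                            "ct_target": float(ct_t),
                            "ct_reference": float(ct_r)})
    table = pd.DataFrame(rows)
    if toy is not None:
        toy.truth.fold_changes = folds
    return table, folds
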