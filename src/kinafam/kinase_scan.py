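"""Candidate MAPK discovery and validation.

Local alignment against reference kinases plus a log-odds profile scan stand
in for the classic BLASTP + profile-HMM search; acceptance then requires the
hallmark features of a plant MAPK: the T[DE]Y activation loop between the
DFG and APE subdomain anchors, enough of the conserved kinase subdomain
anchors, the common-docking (CD) motif region, and a non-fragment length.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# Locatable proxies for the conserved kinase subdomain anchors, searched in
# N->C order. CD is searched only C-terminal of APE.
ANCHOR_PATTERNS = [
    ("GxGxxG", re.compile(r"G.G..[GS]")),
    ("VAIK", re.compile(r"[VAIL]A[VAIL]K")),
    ("HRD", re.compile(r"HRD")),
    ("DFG", re.compile(r"DFG")),
    ("APE", re.compile(r"APE")),
]
TLOOP_RE = re.compile(r"T[DE]Y")
CD_RE = re.compile(r"LH[DE]..[DE]EP.C")


@dataclass
class ScanConfig:
    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    evalue_cutoff: float = 1e-50
    pseudocount: float = 1.0
    min_subdomain_anchors: int = 5
    min_length: int = 300
    min_pssm_bits: float = 20.0

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if not 0 < self.evalue_cutoff <= 1:
            raise ValueError("evalue_cutoff must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class KinaseSignature:
    anchors_found: set = field(default_factory=set)
    anchor_positions: dict = field(default_factory=dict)
    tloop_type: str = "none"
    tloop_pos: int | None = None  # 1-based
    cd_span: tuple[int, int] | None = None  # 1-based inclusive


def _aligner(config: ScanConfig, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(
        config.substitution_matrix)
    # gap of length k costs open + k*extend
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _check_alphabet(seq: str, config: ScanConfig) -> None:
    alphabet = set(str(substitution_matrices.load(
        config.substitution_matrix).alphabet))
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"residues outside matrix alphabet: {sorted(bad)}")


def smith_waterman(query: str, target: str,
                   config: ScanConfig | None = None):
    """Optimal local alignment score with affine gaps.

    Returns (score, ((q_start, q_end), (t_start, t_end))) with 0-based
    half-open spans of the best local alignment; the empty alignment
    (score 0) reports ((0, 0), (0, 0)).
    """
    config = config or ScanConfig()
    if not query or not target:
        raise ValueError("empty sequence")
    _check_alphabet(query, config)
    _check_alphabet(target, config)
    aligner = _aligner(config, "local")
    score = aligner.score(query, target)
    if score <= 0:
        return 0, ((0, 0), (0, 0))
    aln = aligner.align(query, target)[0]
    q_span = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    t_span = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return int(score), (q_span, t_span)


def evalue(score: float, m: int, n: int) -> float:
    """Karlin-Altschul style expect value E = m * n * 2**(-score)."""
    if score < 0:
        raise ValueError("score must be nonnegative")
    log2_e = math.log2(m) + math.log2(n) - score
    return 2.0 ** log2_e


def best_hit(query: str, references: dict[str, str],
             config: ScanConfig | None = None):
    """Best local-alignment hit of query against a reference set.

    Returns (ref_id, score, evalue) using the summed reference length as the
    database size.
    """
    config = config or ScanConfig()
    db_len = sum(len(s) for s in references.values())
    best = (None, 0, math.inf)
    for rid in sorted(references):
        score, _ = smith_waterman(query, references[rid], config)
        e = evalue(score, len(query), db_len)
        if score > best[1]:
            best = (rid, score, e)
    return best


# ------------------------------------------------------------------ PSSM

def build_pssm(seed_alignment: list[str], config: ScanConfig | None = None,
               background: float = 0.05) -> np.ndarray:
    """Log-odds PSSM (bits), width x 20, from a gapless seed alignment."""
    config = config or ScanConfig()
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs >= 2 rows")
    width = len(seed_alignment[0])
    if any(len(r) != width for r in seed_alignment):
        raise ValueError("seed alignment rows differ in length")
    if any("-" in r for r in seed_alignment):
        raise ValueError("gap characters not allowed in seed alignment")
    counts = np.zeros((width, 20))
    for row in seed_alignment:
        for j, a in enumerate(row):
            counts[j, AA_INDEX[a]] += 1
    n = len(seed_alignment)
    p = (counts + config.pseudocount) / (n + 20 * config.pseudocount)
    return np.log2(p / background)


def pssm_scan(protein: str, pssm: np.ndarray) -> tuple[float, int]:
    """Best-window bit score and its 0-based offset (ties -> smallest)."""
    width = pssm.shape[0]
    if len(protein) < width:
        raise ValueError("protein shorter than PSSM width")
    idx = np.array([AA_INDEX[a] for a in protein])
    best_score, best_off = -np.inf, 0
    cols = np.arange(width)
    for off in range(len(protein) - width + 1):
        s = float(pssm[cols, idx[off:off + width]].sum())
        if s > best_score:
            best_score, best_off = s, off
    return best_score, best_off


# ----------------------------------------------------------- signatures

def find_signature(protein: str) -> KinaseSignature:
    """Locate subdomain anchors, the T-loop, and the CD motif.

    Anchors are searched N->C: each search starts where the previous anchor
    ended. The T-loop is the first T[DE]Y strictly between the DFG and APE
    anchors; the CD motif is the first match C-terminal of APE.
    """
    sig = KinaseSignature()
    cursor = 0
    spans: dict[str, tuple[int, int]] = {}
    for name, pattern in ANCHOR_PATTERNS:
        m = pattern.search(protein, cursor)
        if m:
            sig.anchors_found.add(name)
            spans[name] = (m.start(), m.end())
            sig.anchor_positions[name] = m.start() + 1
            cursor = m.end()
    if "DFG" in spans and "APE" in spans:
        dfg_end, ape_start = spans["DFG"][1], spans["APE"][0]
        m = TLOOP_RE.search(protein, dfg_end, ape_start)
        if m:
            sig.tloop_type = m.group(0)
            sig.tloop_pos = m.start() + 1
    if "APE" in spans:
        m = CD_RE.search(protein, spans["APE"][1])
        if m:
            sig.anchors_found.add("CD")
            sig.cd_span = (m.start() + 1, m.end())
    return sig


def validate_candidate(protein: str, hit_evalue: float | None = None,
                       pssm_bits: float | None = None,
                       config: ScanConfig | None = None,
                       signature: KinaseSignature | None = None):
    """Apply the family acceptance rules; returns (accepted, reasons).

    A candidate is accepted when its search hit is significant (E-value at
    or below the cutoff, or profile score at or above the bit threshold),
    it carries a TEY/TDY activation loop, enough subdomain anchors are
    locatable, and it is not a short fragment.
    """
    config = config or ScanConfig()
    sig = signature or find_signature(protein)
    reasons = []
    significant = ((hit_evalue is not None
                    and hit_evalue <= config.evalue_cutoff)
                   or (pssm_bits is not None
                       and pssm_bits >= config.min_pssm_bits))
    if not significant:
        reasons.append("no significant similarity to reference kinases")
    if sig.tloop_type == "none":
        reasons.append("no TEY/TDY activation-loop motif")
    if len(sig.anchors_found) < config.min_subdomain_anchors:
        reasons.append(
            f"only {len(sig.anchors_found)} of 6 subdomain anchors found")
    if len(protein) < config.min_length:
        reasons.append("short polypeptide")
    return (not reasons), reasons
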