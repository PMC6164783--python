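# Methods

This document records what each stage computes, the parameter defaults and
their rationale, what the synthetic-genome generator does and does not
emulate, and the numerical conventions used throughout.

## Coordinate and format conventions

- Genomic intervals are GFF3-style 1-based inclusive everywhere they are
  stored (`GeneModel.exons`, `cds_segments`); conversion to 0-based
  half-open happens only inside slicing helpers.
- FASTA I/O goes through Biopython, GFF3 through gffutils (in-memory DB);
  every CDS feature must reach a `gene` record through its Parent chain.
- Protein positions reported by the signature finder (anchor positions,
  T-loop position, CD span) are 1-based.

## Candidate mining (`kinase_scan`)

A candidate protein is accepted into the family when all four rules hold:

1. **Search significance.** Best local-alignment hit against the reference
   kinase panel (Smith–Waterman, BLOSUM62, affine gaps open 11 / extend 1,
   i.e. a gap of length k costs 11 + k) has expect value
   E = m·n·2^(−S) ≤ 1e−50, with m the query length and n the summed
   reference length. Alternatively a log-odds PSSM window score ≥ 20 bits
   qualifies. The simple 2^(−S) form replaces the full Karlin–Altschul
   statistics; only the binary accept decision is the contract.
2. **Activation loop.** A T[E/D]Y match strictly between the DFG and APE
   anchors.
3. **Subdomain anchors.** At least 5 of 6 locatable anchor motifs, searched
   N→C so each must occur after the previous one: G.G..[GS],
   [VAIL]A[VAIL]K, HRD, DFG, APE, and the common-docking motif
   LH[DE]..[DE]EP.C C-terminal of APE. These anchors are the operational
   proxy for the 11 conserved kinase subdomains.
4. **Length.** ≥ 300 aa, rejecting fragments.

Pairwise alignment itself is delegated to
`Bio.Align.PairwiseAligner` (with `open_gap_score = −(open+extend)`,
`extend_gap_score = −extend` so that a length-k gap costs open + k·extend);
tests verify the scores against exhaustive enumeration of all alignments of
short sequences.

## Alignment and phylogeny (`alignment_phylo`)

- **Progressive MSA.** Pairwise global alignments give p-distances; a UPGMA
  guide tree orders profile–profile Needleman–Wunsch merges. Column scores
  are the average pairwise BLOSUM62 score of the two profiles' residue
  frequency vectors (gap positions carry zero weight); gaps are affine with
  the same 11/1 penalties. The inner DP is vectorized row-wise; the
  horizontal gap state collapses to a prefix maximum.
- **Distances.** p-distance (fraction of mismatching columns) with pairwise
  deletion of gap/X columns; a pair with no comparable columns is an error.
- **Tree.** Saitou–Nei neighbor joining; Q-criterion ties break toward the
  lexicographically smallest taxon pair so results are deterministic;
  negative branch lengths are clamped to 0; the unrooted tree is stored
  with a trifurcating root.
- **Bootstrap.** Felsenstein column resampling (default 200 replicates in
  the pipeline); supports are the percentage of replicate NJ trees
  containing each reference-tree bipartition. Replicates in which some pair
  loses all comparable columns are skipped.
- **Rooting.** Midpoint rooting on the longest leaf-to-leaf path; the
  input tree is never mutated.

## Classification (`classification`)

A query's subfamily is the majority group of the references in the smallest
midpoint-rooted clade containing the query and at least one reference
(ties break lexicographically). The T-loop type is a consistency check: a
TDY loop normally implies group D; a TDY member placed in the group E clade
is reported with a warning but keeps the clade label (the AcMAPK18-like
case), as does any other conflict.

## Gene annotation (`gene_annotation`)

- CDS extraction concatenates CDS segments in ascending genomic order and
  reverse-complements for minus-strand genes; translation uses the standard
  code, excludes the terminal stop, and treats internal stops as errors.
- Molecular weight: Biopython average (Expasy-style) masses.
- Isoelectric point: Bjellqvist pKa set (N-terminal pKa specific to the
  first residue where defined), solved by bisection on the monotone
  net-charge curve to 1e−4 pH. Tests verify |charge(pI)| < 1e−3 against a
  dense pH grid and agreement with Biopython's independent implementation.
- `gene_structure_table` tiles each gene span with alternating exons and
  introns, no gaps or overlaps.

## Motif discovery (`motif_discovery`)

MEME-style ZOOPS (zero-or-one occurrence per sequence) EM with fixed width
(pipeline default 12, 20 motifs): the E-step computes stabilized posterior
site responsibilities against a 0-order background (+1 smoothed), the
M-step re-estimates the PWM (pseudocount 0.01) and the site probability γ.
Starts are chosen MEME-style: candidate windows are converted to sharp PWMs
(0.5 on the seed letter) and ranked by summed best-window log-odds across
sequences, which locks the register; the best of `restarts` (default 3)
fitted models is kept. Found sites (posterior > 0.5) are hard-masked before
searching the next motif; motifs are reported sorted by information
content. Convergence: Δlog-likelihood < 1e−4 or 200 iterations.

## Promoter scanning (`promoter_scan`)

Promoters are the 1500 bp immediately 5′ of the translation start (clipped
with a warning at contig edges; minus-strand promoters are
reverse-complemented genomic sequence 3′ of the CDS end). Elements are
IUPAC patterns scanned with overlapping matches on both strands; a
palindromic pattern therefore reports two hits per physical site. The
packaged element table (ABRE, as-1/TGACG, ERE, W-box, HSE, LTR, MBS,
TC-rich) uses standard PLACE/PlantCARE-style patterns grouped into
hormone / biotic / abiotic categories.

## Expression (`expression`)

2^−ΔΔCt with a reference (actin-like) gene:
ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control. For
time-course treatments the control is the 0 h sample of the same treatment
(0 h normalized to 1); a treatment carrying explicit per-timepoint control
samples (the mock-inoculated pathogen control) uses those instead. The
point estimate uses mean ΔCts; the error bar is the SD of per-replicate
folds paired by replicate index; significance is a two-sided Welch t-test
on replicate ΔCt values (α = 0.05), with constant replicate sets handled
exactly (identical → p = 1). Heatmap rows are clustered by scipy
average-linkage on euclidean distances of log2 folds.

## Synthetic genome generator (`synthetic_data`)

What is controlled exactly is the ground truth every stage is tested
against; sequence realism is deliberately minimal.

- **Proteins.** One consensus scaffold per group A–E: anchor motifs joined
  by linkers drawn from a 15-letter "neutral" alphabet chosen so that no
  anchor, T[D/E]Y or CD match can arise by chance. Members are point
  mutations (rate 0.03) of their group consensus at neutral, non-anchor
  positions; group D (and one AcMAPK18-like group E member) carries TDY,
  all others TEY. C-terminal tail lengths (A 230, B 250, C 220, D 420,
  E 300) give group-typical protein sizes and keep every member above the
  300 aa cutoff. Two references per group form the search/classification
  panel.
- **Decoys.** 10 by default: one third kinase-like sequences with the
  T-X-Y excised (must fail the T-loop rule), the rest random
  neutral-alphabet proteins of 280–420 aa (fail search significance and
  anchors).
- **Genes.** Uniform-codon reverse translation (ATG … TAA), CDS split into
  group-typical exon counts (A 5–7, B 6–8, C 2–3, D 9–11, E 16–29; decoys
  1–3) with GT…AG introns of 60–400 bp, placed round-robin on chr1–chr10
  plus Un, random strand (minus-strand cassettes reverse-complemented with
  coordinates remapped).
- **Promoters.** 1500 bp backgrounds scrubbed of every element match on
  both strands, then elements planted at non-overlapping offsets
  (defaults: 2× as-1/TGACG, 1× W-box, 1× HSE per family gene) and verified
  by re-scanning; a palindromic element counts twice per planted copy.
- **Ct tables.** Per (gene, treatment, timepoint) cell a fold is planted
  (default log2 fold ~ U[−3, 3]; 0 h cells fixed at fold 1); treated
  Ct_target = baseline − log2(fold) + N(0, sd) with sd defaulting to 0.2
  cycles, reference gene constant at 18 up to the same noise. Treatments:
  ABA, ACC, SA, JA, cold, salt at {0, 4, 12, 48} h, heat at {0, 2, 4, 10} h,
  and the pathogen treatment at {24, 48, 96} h with a matched mock control
  per timepoint. Three replicates per cell.
- **Determinism.** Each component draws from
  `np.random.default_rng([seed, k])` with a distinct stream index k, so
  stages are independently reproducible and a pipeline rerun is
  hash-identical.

Not emulated: codon-usage bias, realistic inter-gene divergence profiles,
UTRs/alternative splicing, promoter composition biases, qPCR efficiency
deviations from 2.0, and inter-replicate correlation.

## Limitations

- The search-significance model is a toy E-value; absolute E-values are not
  comparable to BLAST, only the threshold behaviour is.
- Progressive MSA has no iterative refinement; deep cross-group alignments
  of the synthetic linkers are not meaningful, and the classification
  relies on clade membership rather than alignment quality.
- Bootstrap supports on the synthetic data are stable for clades with
  signal but should not be interpreted biologically.
- The pI model uses a single generic N-terminal pKa for residues without a
  Bjellqvist-specific value; agreement with other implementations is ~0.3
  pH for random 200-mers.
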