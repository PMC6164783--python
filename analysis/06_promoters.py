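#!/usr/bin/env python
"""Step 6: extract 1500 bp upstream promoters and count cis-regulatory
elements (both strands, overlapping matches included)."""

import argparse
from pathlib import Path

from kinafam import io_formats, promoter_scan


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    ap.add_argument("--length", type=int, default=1500)
    args = ap.parse_args()

    genome = {r.id: r.sequence
              for r in io_formats.read_fasta(args.results / "genome.fasta")}
    genes = io_formats.read_gff3(args.results / "annotation.gff3")
    elements = promoter_scan.packaged_element_table()
    promoters = [promoter_scan.extract_upstream(g, genome, args.length)
                 for g in genes if g.cds_segments]
    counts, totals = promoter_scan.count_elements(promoters, elements)
    counts.to_csv(args.results / "element_counts.tsv", sep="\t")
    totals.to_csv(args.results / "element_category_totals.tsv", sep="\t")
    print(f"{counts.shape[0]} promoters x {counts.shape[1]} elements "
          f"-> element_counts.tsv")


if __name__ == "__main__":
    main()
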