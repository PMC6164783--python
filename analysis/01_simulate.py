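#!/usr/bin/env python
"""Step 1: generate the synthetic genome, annotation, proteins, promoters
and qPCR Ct table, with full ground truth for the later steps."""

import argparse
from pathlib import Path

from kinafam import io_formats, promoter_scan, synthetic_data


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    elements = promoter_scan.packaged_element_table()
    toy = synthetic_data.generate_toy_genome(
        synthetic_data.SynthConfig(seed=args.seed), elements)
    promoters, element_truth = synthetic_data.plant_promoter_elements(
        toy, elements)
    ct_table, _ = synthetic_data.simulate_ct_table(toy)

    io_formats.write_fasta(toy.genome_records, args.out / "genome.fasta")
    io_formats.write_gff3(toy.annotation, args.out / "annotation.gff3")
    io_formats.write_fasta(toy.proteins, args.out / "proteins.fasta")
    io_formats.write_fasta(toy.references, args.out / "references.fasta")
    io_formats.write_fasta(promoters, args.out / "promoters.fasta")
    with open(args.out / "ref_groups.tsv", "w") as fh:
        fh.write("ref_id\tgroup\n")
        for rid, group in sorted(toy.ref_groups.items()):
            fh.write(f"{rid}\t{group}\n")
    toy.truth.members.to_csv(args.out / "truth_members.tsv", sep="\t",
                             index=False)
    element_truth.to_csv(args.out / "truth_elements.tsv", sep="\t")
    ct_table.to_csv(args.out / "ct_table.tsv", sep="\t", index=False)
    print(f"simulated {len(toy.annotation)} genes "
          f"({len(toy.truth.members)} family members, "
          f"{len(toy.truth.decoys)} decoys) -> {args.out}")


if __name__ == "__main__":
    main()
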