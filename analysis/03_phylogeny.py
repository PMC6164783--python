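#!/usr/bin/env python
"""Step 3: progressive MSA of the accepted kinases plus references,
p-distances, and a neighbor-joining tree with bootstrap supports."""

import argparse
from pathlib import Path

import pandas as pd

from kinafam import alignment_phylo, io_formats


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    ap.add_argument("--bootstrap", type=int, default=200)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    scan = pd.read_csv(args.results / "scan.tsv", sep="\t")
    accepted = set(scan[scan.accepted].id)
    seqs = {r.id: r.sequence
            for r in io_formats.read_fasta(args.results / "proteins.fasta")
            if r.id in accepted}
    seqs.update({r.id: r.sequence for r in
                 io_formats.read_fasta(args.results / "references.fasta")})

    msa = alignment_phylo.progressive_msa(seqs)
    io_formats.write_fasta(
        [io_formats.SeqRecord(id=i, sequence=msa.rows[i]) for i in msa.ids],
        args.results / "aligned.fasta")
    d = alignment_phylo.p_distance(msa)
    pd.DataFrame(d.matrix, index=d.ids, columns=d.ids).to_csv(
        args.results / "distances.tsv", sep="\t")
    tree = alignment_phylo.bootstrap_support(msa, n_reps=args.bootstrap,
                                             seed=args.seed)
    (args.results / "tree.nwk").write_text(
        io_formats.write_newick(tree) + "\n")
    print(f"aligned {len(seqs)} sequences, NJ tree with "
          f"{args.bootstrap} bootstrap replicates -> tree.nwk")


if __name__ == "__main__":
    main()
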