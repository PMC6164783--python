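#!/usr/bin/env python
"""Step 4: assign subfamilies (A-E) from the tree, extract and translate
each accepted gene's CDS, and assemble the family roster table."""

import argparse
from pathlib import Path

import pandas as pd

from kinafam import classification, gene_annotation, io_formats


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    scan = pd.read_csv(args.results / "scan.tsv", sep="\t")
    accepted = sorted(scan[scan.accepted].id)
    tloops = dict(zip(scan.id, scan.tloop))
    tree = io_formats.parse_newick(
        (args.results / "tree.nwk").read_text())
    panel = dict(pd.read_csv(args.results / "ref_groups.tsv",
                             sep="\t").itertuples(index=False))
    groups = classification.assign_all(tree, tloops, panel)

    genome = {r.id: r.sequence
              for r in io_formats.read_fasta(args.results / "genome.fasta")}
    annotations = {g.gene_id: g for g in
                   io_formats.read_gff3(args.results / "annotation.gff3")}
    proteins = {gid: gene_annotation.translate(
        gene_annotation.extract_cds(annotations[gid], genome))
        for gid in accepted}
    table = classification.build_family_table(
        accepted, annotations, proteins, tloops, groups)
    io_formats.write_family_table(table, args.results / "family_table.tsv")
    structure = gene_annotation.gene_structure_table(
        [annotations[gid] for gid in accepted])
    pd.DataFrame(structure).to_csv(args.results / "gene_structure.tsv",
                                   sep="\t", index=False)
    by_group = pd.Series(groups).value_counts().sort_index()
    print(f"{len(table)} family members; group sizes: "
          + ", ".join(f"{g}={n}" for g, n in by_group.items()))


if __name__ == "__main__":
    main()
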