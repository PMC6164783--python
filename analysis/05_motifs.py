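#!/usr/bin/env python
"""Step 5: de novo ZOOPS EM motif discovery on the accepted kinases and
the per-protein motif architecture."""

import argparse
from pathlib import Path

import pandas as pd

from kinafam import io_formats, motif_discovery


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    ap.add_argument("--width", type=int, default=12)
    ap.add_argument("--n-motifs", type=int, default=20)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    scan = pd.read_csv(args.results / "scan.tsv", sep="\t")
    accepted = set(scan[scan.accepted].id)
    seqs = {r.id: r.sequence
            for r in io_formats.read_fasta(args.results / "proteins.fasta")
            if r.id in accepted}
    family = io_formats.read_family_table(args.results / "family_table.tsv")
    groups = {r.gene_id: r.group for r in family}

    motifs = motif_discovery.em_motif_search(
        seqs, width=args.width, n_motifs=args.n_motifs, seed=args.seed)
    bg = motif_discovery._background(motif_discovery._encode(seqs))
    motif_discovery.write_meme_minimal(motifs, bg,
                                       args.results / "motifs.meme")
    presence, shared = motif_discovery.motif_architecture(seqs, motifs,
                                                          groups=groups)
    pd.DataFrame([
        {"gene_id": gid, "group": groups.get(gid, ""),
         "motifs": ";".join(f"{mi}@{off}" for mi, off in hits)}
        for gid, hits in presence.items()]).to_csv(
        args.results / "motif_architecture.tsv", sep="\t", index=False)
    print(f"{len(motifs)} motifs -> motifs.meme; shared per group: "
          + "; ".join(f"{g}:{sorted(m)}" for g, m in sorted(shared.items())))


if __name__ == "__main__":
    main()
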