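#!/usr/bin/env python
"""Step 2: search every candidate protein against the reference kinases and
apply the family acceptance rules (T-loop, subdomain anchors, length)."""

import argparse
from pathlib import Path

import pandas as pd

from kinafam import io_formats, kinase_scan


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = kinase_scan.ScanConfig()
    refs = {r.id: r.sequence
            for r in io_formats.read_fasta(args.results / "references.fasta")}
    rows = []
    for rec in io_formats.read_fasta(args.results / "proteins.fasta"):
        rid, score, e = kinase_scan.best_hit(rec.sequence, refs, cfg)
        sig = kinase_scan.find_signature(rec.sequence)
        ok, reasons = kinase_scan.validate_candidate(
            rec.sequence, hit_evalue=e, config=cfg, signature=sig)
        rows.append({"id": rec.id, "best_ref": rid, "score": score,
                     "evalue": e, "tloop": sig.tloop_type,
                     "anchors": ",".join(sorted(sig.anchors_found)),
                     "accepted": ok, "reasons": "; ".join(reasons)})
    df = pd.DataFrame(rows)
    df.to_csv(args.results / "scan.tsv", sep="\t", index=False)
    print(f"accepted {int(df.accepted.sum())}/{len(df)} candidates "
          f"-> {args.results / 'scan.tsv'}")


if __name__ == "__main__":
    main()
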