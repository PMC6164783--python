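#!/usr/bin/env python
"""Step 7: 2^-ddCt relative expression from the Ct table, significance
calls, and a clustered log2 fold-change heatmap matrix."""

import argparse
from pathlib import Path

import pandas as pd

from kinafam import expression


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    ct = pd.read_csv(args.results / "ct_table.tsv", sep="\t")
    fcm = expression.delta_delta_ct(ct)
    fcm.to_csv(args.results / "fold_changes.tsv", sep="\t", index=False)
    wide = expression.log2_matrix(fcm)
    order, _ = expression.cluster_rows(wide)
    expression.heatmap_export(wide, order, args.results / "log2_heatmap.tsv")
    n_sig = int(fcm.significant.fillna(False).sum())
    print(f"{len(fcm)} fold-change cells ({n_sig} significant) "
          f"-> fold_changes.tsv, log2_heatmap.tsv")


if __name__ == "__main__":
    main()
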