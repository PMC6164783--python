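"""qRT-PCR relative expression: 2^-ddCt folds, significance, clustering.

Fold changes follow the comparative-Ct method with a reference
(housekeeping) gene: ddCt = (Ct_target - Ct_ref)_treated -
(Ct_target - Ct_ref)_control, fold = 2^-ddCt. For time-course treatments the
control is the 0 h sample of the same treatment (0 h normalized to 1); when
a treatment carries explicit per-timepoint control samples (e.g. a
mock-inoculated pathogen control) those are used instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

CT_COLUMNS = ["gene", "treatment", "timepoint", "replicate", "condition",
              "ct_target", "ct_reference"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    for col in ("ct_target", "ct_reference"):
        vals = table[col]
        if ((vals <= 0) | (vals >= 45)).any():
            raise ValueError(f"{col}: Ct values must lie in (0, 45)")
    return table


def _delta_ct(rows: pd.DataFrame) -> np.ndarray:
    return (rows["ct_target"] - rows["ct_reference"]).to_numpy()


def _control_rows(table: pd.DataFrame, gene: str, treatment: str,
                  timepoint: float) -> pd.DataFrame:
    """Matched baseline: per-timepoint control if present, else the 0 h cell."""
    sel = table[(table["gene"] == gene) & (table["treatment"] == treatment)]
    ctrl = sel[(sel["condition"] == "control")
               & (sel["timepoint"] == timepoint)]
    if len(ctrl):
        return ctrl
    ctrl = sel[(sel["timepoint"] == 0) & (sel["condition"] == "treated")]
    if not len(ctrl):
        raise ValueError(f"no control cell for {gene}/{treatment}"
                         f"/{timepoint} h")
    return ctrl


def delta_delta_ct(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fold-change matrix in long form.

    One row per (gene, treatment, timepoint): fold (from mean dCts), sd
    (across replicate folds paired by index), log2fold, p-value and
    significance flag (Welch t on replicate dCt values).
    """
    table = validate_ct_table(table)
    out = []
    treated = table[table["condition"] == "treated"]
    for (gene, trt, tp), rows in treated.groupby(
            ["gene", "treatment", "timepoint"], sort=True):
        ctrl = _control_rows(table, gene, trt, tp)
        d_t, d_c = _delta_ct(rows), _delta_ct(ctrl)
        ddct = d_t.mean() - d_c.mean()
        fold = float(2.0 ** -ddct)
        k = min(len(d_t), len(d_c))
        rep_folds = 2.0 ** -(d_t[:k] - d_c[:k])
        sd = float(np.std(rep_folds, ddof=1)) if k > 1 else float("nan")
        p, flag = significance(d_t, d_c, alpha)
        out.append({"gene": gene, "treatment": trt, "timepoint": tp,
                    "fold": fold, "sd": sd,
                    "log2fold": float(np.log2(fold)),
                    "p_value": p, "significant": flag})
    return pd.DataFrame(out)


def significance(treated_dct: np.ndarray, control_dct: np.ndarray,
                 alpha: float = 0.05):
    """Two-sided Welch t-test on replicate dCt values -> (p, flag)."""
    t, c = np.asarray(treated_dct, float), np.asarray(control_dct, float)
    if len(t) < 2 or len(c) < 2:
        return float("nan"), None
    if np.array_equal(np.sort(t), np.sort(c)):
        return 1.0, False
    if np.ptp(t) == 0 and np.ptp(c) == 0:  # both replicate sets constant
        return (1.0, False) if t[0] == c[0] else (0.0, True)
    p = float(stats.ttest_ind(t, c, equal_var=False).pvalue)
    return p, bool(p < alpha)


def log2_matrix(fcm: pd.DataFrame) -> pd.DataFrame:
    """Wide gene x (treatment, timepoint) matrix of log2 fold changes."""
    if (fcm["fold"] <= 0).any():
        raise ValueError("fold changes must be positive")
    wide = fcm.pivot_table(index="gene", columns=["treatment", "timepoint"],
                           values="log2fold")
    return wide


def cluster_rows(matrix: pd.DataFrame, method: str = "average",
                 metric: str = "euclidean"):
    """Agglomerative row clustering -> (leaf order, scipy linkage matrix)."""
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError("matrix contains non-finite values")
    if len(matrix) == 1:
        return list(matrix.index), None
    Z = hierarchy.linkage(matrix.to_numpy(), method=method, metric=metric)
    order = hierarchy.leaves_list(Z)
    return [matrix.index[i] for i in order], Z


def heatmap_export(matrix: pd.DataFrame, order: list[str], path) -> None:
    """Reordered log2 matrix with flattened column labels, as TSV."""
    out = matrix.loc[order]
    out.columns = [f"{t}_{tp}h" for t, tp in out.columns]
    out.to_csv(path, sep="\t")
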