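"""Relative qPCR quantification by the 2^-ddCt method, plus Grubbs screening.

dCt_i = Ct(target, sample i) - Ct(reference, sample i); ddCt is the difference
of group means of dCt (case - control), and the fold-change is 2^-ddCt.
Per-sample relative quantities 2^-(dCt_i - mean dCt_control) are reported so
the control-group geometric mean is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import rank_correlation

__all__ = ["DdctResult", "ddct_fold_change", "grubbs_test", "correlate_mir_target"]

CT_COLUMNS = ("sample_id", "group_label", "assay", "ct")


@dataclass
class DdctResult:
    case_group: str
    control_group: str
    dct: pd.DataFrame  # sample_id, group_label, dct, rel_quantity
    mean_dct_case: float
    mean_dct_control: float
    ddct: float
    fold_change: float
    test: dict = field(default_factory=dict)


def _dct_per_sample(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    wide = ct.pivot_table(
        index=["sample_id", "group_label"], columns="assay", values="ct",
        aggfunc="mean",
    )
    for assay in ("target", "reference"):
        if assay not in wide.columns or wide[assay].isna().any():
            bad = wide.index.tolist() if assay not in wide.columns else \
                wide.index[wide[assay].isna()].tolist()
            raise ValueError(f"samples missing {assay!r} assay: {bad}")
    out = wide.reset_index()
    out["dct"] = out["target"] - out["reference"]
    return out[["sample_id", "group_label", "dct"]]


def ddct_fold_change(ct: pd.DataFrame, case_group: str,
                     control_group: str) -> DdctResult:
    """Fold-change of the case group relative to control by 2^-ddCt.

    ddCt is computed from group means of dCt (the standard Livak
    formulation).  A Mann-Whitney U test on per-sample dCt values is attached.
    """
    dct = _dct_per_sample(ct)
    groups = set(dct["group_label"])
    for g in (case_group, control_group):
        if g not in groups:
            raise ValueError(f"unknown group {g!r}; have {sorted(groups)}")
    case = dct.loc[dct.group_label == case_group, "dct"].to_numpy()
    control = dct.loc[dct.group_label == control_group, "dct"].to_numpy()
    mean_case = float(case.mean())
    mean_control = float(control.mean())
    ddct = mean_case - mean_control
    keep = dct.group_label.isin([case_group, control_group])
    dct = dct.loc[keep].copy()
    dct["rel_quantity"] = 2.0 ** -(dct["dct"] - mean_control)
    from .stats import mann_whitney  # local import avoids cycle at module load
    test = mann_whitney(case, control)
    return DdctResult(
        case_group=case_group,
        control_group=control_group,
        dct=dct,
        mean_dct_case=mean_case,
        mean_dct_control=mean_control,
        ddct=float(ddct),
        fold_change=float(2.0 ** -ddct),
        test={"statistic": test.statistic, "p": test.p_value,
              "method": test.method, "exact": test.exact},
    )


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05) -> dict:
    """Single-pass two-sided Grubbs test for one outlier.

    G = max |x_i - mean| / s with the sample (n-1) standard deviation,
    compared against the t-based critical value at level ``alpha``.  No
    iterative removal is performed.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("Grubbs test undefined for zero-variance data")
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    g = float(dev[idx] / s)
    gcrit = float(grubbs_critical(x.size, alpha))
    return {
        "is_outlier": g > gcrit,
        "index": idx if g > gcrit else None,
        "G": g,
        "G_critical": gcrit,
        "alpha": alpha,
        "n": int(x.size),
    }


def correlate_mir_target(mir_values, target_values) -> dict:
    """Spearman correlation between paired miRNA and target mRNA levels."""
    return rank_correlation(mir_values, target_values)
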