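"""Single-feature ROC diagnostics.

The AUC is the normalized Mann-Whitney U statistic: the probability that a
random case sample outranks a random control sample, ties counting one half.
The orientation is fixed (case = positive); AUC below 0.5 is reported as-is
with the direction noted, and thresholds are applied to max(auc, 1 - auc)
only when the caller opts into flipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, InputError


@dataclass
class ROCRecord:
    feature_id: str
    auc: float
    n_pos: int
    n_neg: int
    direction: str  # "case_high" or "case_low"
    curve: list[tuple[float, float]]  # ordered (FPR, TPR)


def auc(values, labels, feature_id: str = "feature") -> ROCRecord:
    """ROC record for one feature; ``labels`` is boolean (True = positive)."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC needs at least one sample in each class")
    ranks = stats.rankdata(x)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    a = float(u / (n_pos * n_neg))
    # ROC curve: thresholds at each distinct value, descending
    order = np.argsort(-x, kind="stable")
    y_sorted = y[order]
    x_sorted = x[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    distinct = np.r_[np.diff(x_sorted) != 0, True]
    curve = [(0.0, 0.0)] + [
        (float(fp) / n_neg, float(tp) / n_pos)
        for fp, tp in zip(fps[distinct], tps[distinct])
    ]
    return ROCRecord(
        feature_id=feature_id, auc=a, n_pos=n_pos, n_neg=n_neg,
        direction="case_high" if a >= 0.5 else "case_low", curve=curve,
    )


def per_feature_auc(
    matrix: ExpressionMatrix,
    case: str,
    control: str,
    auc_min: float = 0.7,
    allow_flip: bool = False,
) -> pd.DataFrame:
    """One ROC record per feature, case vs control, with pass flags.

    With ``allow_flip`` the pass threshold is applied to max(auc, 1 - auc),
    treating strongly case-low features as diagnostic too.
    """
    case_cols = matrix.group_samples(case)
    ctrl_cols = matrix.group_samples(control)
    if not case_cols or not ctrl_cols:
        raise InputError(f"groups {case!r}/{control!r} missing from matrix")
    cols = case_cols + ctrl_cols
    labels = np.array([True] * len(case_cols) + [False] * len(ctrl_cols))
    rows = []
    for feature in matrix.feature_ids:
        rec = auc(matrix.values.loc[feature, cols].to_numpy(dtype=float), labels,
                  feature_id=feature)
        effective = max(rec.auc, 1.0 - rec.auc) if allow_flip else rec.auc
        rows.append({
            "feature": feature, "auc": rec.auc, "direction": rec.direction,
            "n_pos": rec.n_pos, "n_neg": rec.n_neg,
            "passes": effective > auc_min,
            "pass_0.7": (max(rec.auc, 1 - rec.auc) if allow_flip else rec.auc) > 0.7,
            "pass_0.9": (max(rec.auc, 1 - rec.auc) if allow_flip else rec.auc) > 0.9,
        })
    return pd.DataFrame(rows)


def curve_table(record: ROCRecord) -> pd.DataFrame:
    return pd.DataFrame(record.curve, columns=["fpr", "tpr"])
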