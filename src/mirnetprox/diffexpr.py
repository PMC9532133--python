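"""Two-group differential expression with empirical-Bayes variance moderation.

The moderated t-statistic shrinks each feature's pooled residual variance
toward a prior variance estimated from all features (a scaled inverse-chi-
square prior fitted by moment matching on the log sample variances, the
standard microarray empirical-Bayes scheme). With prior degrees of freedom
d0 the moderated variance is

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t is referred to a t distribution with d0 + d_g degrees of
freedom. At d0 = 0 this reduces exactly to the ordinary pooled-variance
two-sample t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, InputError


class InsufficientReplicatesError(InputError):
    pass


class DegenerateInputError(InputError):
    pass


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    # Newton iteration for y with trigamma(y) = x (monotone decreasing).
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * abs(y):
            break
    return float(y)


def estimate_prior(sample_vars: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0^2) on log sample variances.

    Returns (prior_df, prior_var); prior_df may be ``inf`` when the observed
    spread of log variances is no larger than expected under a common
    variance.
    """
    s2 = np.asarray(sample_vars, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise DegenerateInputError("every feature has zero residual variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = float(np.mean(e))
    if e.size < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1))
    rhs = e_var - float(special.polygamma(1, df_resid / 2.0))
    if rhs <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(rhs)
    s0 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0)


def moderated_t(
    matrix: ExpressionMatrix,
    case: str,
    control: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t-test of ``case`` vs ``control`` groups.

    Parameters
    ----------
    matrix : ExpressionMatrix
        log2 expression with group labels.
    case, control : str
        Group labels; log2 fold change is case mean minus control mean.
    prior_df : float, optional
        Force the prior degrees of freedom (0 recovers the ordinary pooled
        t-test; ``None`` estimates it from the data).

    Returns
    -------
    pandas.DataFrame
        Columns feature, log2fc, t_stat, p_value, fdr, direction (set to
        ``ns`` here; :func:`filter_de` assigns up/down).
    """
    case_cols = matrix.group_samples(case)
    ctrl_cols = matrix.group_samples(control)
    n1, n0 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n0 < 2:
        raise InsufficientReplicatesError(
            f"need >=2 samples per group, got {case}={n1}, {control}={n0}"
        )
    x1 = matrix.values[case_cols].to_numpy(dtype=float)
    x0 = matrix.values[ctrl_cols].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m0 = x0.mean(axis=1)
    lfc = m1 - m0
    df_resid = n1 + n0 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x0 - m0[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0 = estimate_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0 = estimate_prior(s2, df_resid)[1] if d0 > 0 else 0.0
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0)
        df_total = 1e12  # effectively normal reference
    else:
        s2_mod = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    if np.all(s2_mod == 0):
        raise DegenerateInputError("zero moderated variance for every feature")

    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "log2fc": lfc,
            "t_stat": t,
            "p_value": p,
            "fdr": bh_adjust(p),
            "direction": "ns",
        }
    )


def filter_de(
    records: pd.DataFrame,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    criterion: str = "fdr",
) -> pd.DataFrame:
    """Assign up/down/ns directions using strict threshold inequalities.

    A feature is significant iff |log2fc| > lfc_min (strict) and the chosen
    statistic (``fdr`` or ``raw_p``) is < alpha (strict).
    """
    if criterion not in ("fdr", "raw_p"):
        raise ValueError(f"criterion must be 'fdr' or 'raw_p', got {criterion!r}")
    col = "fdr" if criterion == "fdr" else "p_value"
    out = records.copy()
    sig = (out["log2fc"].abs() > lfc_min) & (out[col] < alpha)
    out["direction"] = np.where(
        sig & (out["log2fc"] > 0), "up", np.where(sig & (out["log2fc"] < 0), "down", "ns")
    )
    return out


def significant_features(records: pd.DataFrame) -> list[str]:
    return list(records.loc[records["direction"] != "ns", "feature"])


def merge_contrasts(de_lists: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of significant features across contrasts.

    A feature significant in several contrasts keeps the direction of the
    contrast where it has the smallest p-value; features whose per-contrast
    directions disagree are flagged.
    """
    rows = []
    for contrast, df in de_lists.items():
        sub = df[df["direction"] != "ns"]
        for _, r in sub.iterrows():
            rows.append(
                {
                    "feature": r["feature"],
                    "direction": r["direction"],
                    "p_value": r["p_value"],
                    "log2fc": r["log2fc"],
                    "contrast": contrast,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["feature", "direction", "p_value", "log2fc", "contrast", "conflict"]
        )
    all_hits = pd.DataFrame(rows)
    merged = []
    for feature, sub in all_hits.groupby("feature", sort=True):
        best = sub.loc[sub["p_value"].idxmin()]
        merged.append(
            {
                "feature": feature,
                "direction": best["direction"],
                "p_value": best["p_value"],
                "log2fc": best["log2fc"],
                "contrast": best["contrast"],
                "conflict": sub["direction"].nunique() > 1,
            }
        )
    return pd.DataFrame(merged)
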