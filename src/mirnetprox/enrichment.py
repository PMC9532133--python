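"""Over-representation analysis and single-sample gene-set enrichment scoring.

ORA is the upper-tail hypergeometric test of a gene list against each set
within a background universe. The per-sample scorer is the rank-weighted
running-sum enrichment statistic (ssGSEA): within each sample genes are
ranked by expression, and the score accumulates the difference between the
weighted in-set cumulative distribution (weights = rank^alpha) and the
unweighted out-of-set cumulative distribution. Scores depend only on
within-sample ranks and are therefore invariant under strictly increasing
per-sample transforms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


def ora(
    gene_list,
    collection: GeneSetCollection,
    universe=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    p = P(X >= k) with N = |universe|, K = |set ∩ universe|,
    n = |list ∩ universe|, k = |list ∩ set ∩ universe|; BH across sets.
    """
    if universe is None:
        universe = collection.universe
    if not universe:
        raise ValueError("ORA requires a nonempty universe")
    uni = set(universe)
    genes = set(gene_list) & uni
    n = len(genes)
    N = len(uni)
    if n == 0:
        logger.warning("ORA: empty effective gene list after universe intersection")
        return pd.DataFrame(
            columns=["set_name", "overlap_k", "set_in_universe_K", "list_n",
                     "universe_N", "p_value", "fdr", "significant"]
        )
    rows = []
    for name in collection.names():
        members = set(collection[name]) & uni
        K = len(members)
        k = len(genes & members)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"set_name": name, "overlap_k": k, "set_in_universe_K": K,
             "list_n": n, "universe_N": N, "p_value": min(max(p, np.finfo(float).tiny), 1.0)}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"])
    out["significant"] = out["p_value"] < alpha
    return out


def _ssgsea_sample(ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum score for one sample.

    ranks: rank statistic per gene (higher = more expressed);
    in_set: boolean membership mask.
    """
    order = np.argsort(-ranks, kind="stable")
    r_sorted = ranks[order]
    mask = in_set[order]
    w = np.abs(r_sorted) ** alpha
    w_in = np.where(mask, w, 0.0)
    denom_in = w_in.sum()
    n_out = int((~mask).sum())
    if denom_in == 0 or n_out == 0:
        return float("nan")
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~mask) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-sample enrichment scores (sets x samples).

    Sets with no gene present in the matrix are omitted (logged). With
    ``normalize`` the whole score matrix is divided by its range across all
    sets and samples.
    """
    feats = pd.Index(matrix.feature_ids)
    x = matrix.values.to_numpy(dtype=float)
    # average ranks within each sample, ties averaged
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    rows = {}
    for name in collection.names():
        present = feats.isin(collection[name])
        if present.sum() == 0:
            logger.warning("ssgsea: set %s has no genes in the matrix; omitted", name)
            continue
        if present.all():
            logger.warning("ssgsea: set %s covers the whole matrix; omitted", name)
            continue
        rows[name] = [
            _ssgsea_sample(ranks[:, j], present, alpha) for j in range(x.shape[1])
        ]
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.sample_ids)
    if normalize and scores.size:
        rng_ = float(scores.to_numpy().max() - scores.to_numpy().min())
        if rng_ > 0:
            scores = scores / rng_
    return scores


def score_group_test(
    scores: pd.DataFrame,
    groups: pd.Series,
    case: str,
    control: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test of each set's scores between two groups."""
    case_cols = [s for s in scores.columns if groups.get(s) == case]
    ctrl_cols = [s for s in scores.columns if groups.get(s) == control]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("score_group_test needs >=2 samples in each group")
    rows = []
    for name, row in scores.iterrows():
        a = row[case_cols].to_numpy(dtype=float)
        b = row[ctrl_cols].to_numpy(dtype=float)
        zero_var = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if zero_var:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"set_name": name, "t_stat": float(t), "p_value": float(p),
                     "zero_variance": zero_var})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].clip(lower=np.finfo(float).tiny))
        out["significant"] = out["p_value"] < alpha
    return out
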