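"""Gene-prioritization logic: composite pathway scores, correlation screens,
multi-evidence intersection, trend/ANOVA filters, and median-split tests.

Correlation p-values use the exact t transform of the Pearson coefficient,
t = r * sqrt((m - 2) / (1 - r^2)) on m - 2 degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix


def composite_mean(scores: pd.DataFrame, set_names: list[str], name: str) -> pd.Series:
    """Sample-wise arithmetic mean of several pathway score vectors."""
    missing = [s for s in set_names if s not in scores.index]
    if missing:
        raise KeyError(f"score rows not found: {missing}")
    out = scores.loc[set_names].mean(axis=0)
    out.name = name
    return out


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its t-transform p-value; (nan, nan) on zero variance."""
    m = len(x)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0 or m < 3:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((m - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), m - 2)
    return r, float(p)


def pearson_screen(
    matrix: ExpressionMatrix,
    score: pd.Series,
    r_min: float = 0.4,
    p_max: float = 0.05,
    absolute: bool = True,
) -> pd.DataFrame:
    """Correlate every gene with a per-sample score vector.

    ``absolute`` applies |r| > r_min (both signs count); otherwise the
    threshold is one-sided, r > r_min. Zero-variance genes are emitted with a
    flag, never dropped.
    """
    samples = [s for s in matrix.sample_ids if s in score.index]
    if len(samples) < 3:
        raise ValueError("pearson_screen needs >=3 aligned samples")
    y = score.loc[samples].to_numpy(dtype=float)
    rows = []
    score_name = score.name if score.name is not None else "score"
    for gene in matrix.feature_ids:
        x = matrix.values.loc[gene, samples].to_numpy(dtype=float)
        r, p = pearson_with_p(x, y)
        undefined = np.isnan(r)
        if undefined:
            sig = False
        else:
            strength = abs(r) if absolute else r
            sig = (strength > r_min) and (p < p_max)
        rows.append({"gene": gene, "score_name": score_name, "r": r, "p_value": p,
                     "significant": sig, "zero_variance": undefined})
    return pd.DataFrame(rows)


def significant_genes(screen: pd.DataFrame) -> set[str]:
    return set(screen.loc[screen["significant"], "gene"])


def evidence_intersection(screens: dict[str, set]) -> list[str]:
    """Genes significant in every evidence category (e.g. hypoxia AND
    energy AND inflammation; a category built from several screens should be
    passed as their union)."""
    if not screens:
        return []
    sets = [set(v) for v in screens.values()]
    common = set.intersection(*sets)
    return sorted(common)


def anova_groups(matrix: ExpressionMatrix, gene: str, groups: list[str]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a gene across >=2 groups."""
    samples_by_group = [matrix.group_samples(g) for g in groups]
    if any(len(s) < 2 for s in samples_by_group):
        raise ValueError("anova_groups needs >=2 samples per group")
    vectors = [matrix.values.loc[gene, s].to_numpy(dtype=float) for s in samples_by_group]
    allvals = np.concatenate(vectors)
    if np.ptp(allvals) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*vectors)
    return float(f), float(p)


def monotone_trend(matrix: ExpressionMatrix, gene: str, ordered_groups: list[str]) -> str:
    """Strict monotonicity of group means along the given group order."""
    means = [
        float(matrix.values.loc[gene, matrix.group_samples(g)].mean())
        for g in ordered_groups
    ]
    if all(a > b for a, b in zip(means, means[1:])):
        return "decreasing"
    if all(a < b for a, b in zip(means, means[1:])):
        return "increasing"
    return "none"


def trend_anova_filter(
    matrix: ExpressionMatrix,
    genes: list[str],
    ordered_groups: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Strict monotone trend plus one-way ANOVA p < alpha, per gene."""
    rows = []
    for gene in genes:
        trend = monotone_trend(matrix, gene, ordered_groups)
        f, p = anova_groups(matrix, gene, ordered_groups)
        rows.append({"gene": gene, "trend": trend, "f_stat": f, "p_value": p,
                     "passes": trend != "none" and p < alpha})
    return pd.DataFrame(rows)


def gene_neighborhood(
    matrix: ExpressionMatrix,
    anchor_gene: str,
    r_min: float = 0.4,
    p_max: float = 0.001,
) -> list[str]:
    """Genes positively co-expressed with an anchor gene (signed r > r_min,
    p < p_max), excluding the anchor itself. This set plays the role of the
    disease gene set S in the proximity screen."""
    if anchor_gene not in matrix.values.index:
        raise KeyError(f"anchor gene {anchor_gene!r} not in matrix")
    anchor = matrix.values.loc[anchor_gene]
    anchor.name = anchor_gene
    screen = pearson_screen(matrix, anchor, r_min=r_min, p_max=p_max, absolute=False)
    hits = screen.loc[screen["significant"], "gene"]
    return sorted(g for g in hits if g != anchor_gene)


def median_split_test(
    matrix: ExpressionMatrix,
    gene: str,
    scores: pd.DataFrame,
) -> pd.DataFrame:
    """Median split of samples by a gene's expression (ties to the low
    group); Welch t per pathway score between the halves, plus the Pearson
    correlation of each score with the gene's expression."""
    if len(matrix.sample_ids) < 4:
        raise ValueError("median_split_test needs >=4 samples")
    expr = matrix.values.loc[gene]
    med = float(expr.median())
    low = [s for s in matrix.sample_ids if expr[s] <= med]
    high = [s for s in matrix.sample_ids if expr[s] > med]
    rows = []
    for name, row in scores.iterrows():
        a = row[high].to_numpy(dtype=float) if len(high) else np.array([])
        b = row[low].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            t, p = float("nan"), float("nan")
        elif np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        r, r_p = pearson_with_p(
            row[matrix.sample_ids].to_numpy(dtype=float),
            expr[matrix.sample_ids].to_numpy(dtype=float),
        )
        rows.append({"set_name": name, "t_stat": float(t), "p_value": float(p),
                     "r": r, "r_p_value": r_p})
    return pd.DataFrame(rows)
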