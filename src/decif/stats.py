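"""Agreement and association statistics shared across the pipeline.

Cohen's kappa with an asymptotic 95% CI and Landis–Koch qualitative bands,
Fisher's exact test, the Kruskal–Wallis test (with an exact two-group
permutation option for small samples), Spearman correlation with a
Fisher-z confidence interval, the CD3 first-principal-component surrogate
score, and percentage-marker dichotomizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionMatrix

__all__ = [
    "AgreementResult",
    "MarkerDichotomy",
    "cohen_kappa",
    "landis_koch_label",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "spearman_ci",
    "cd3_pca_score",
    "dichotomize_marker",
    "cd45_normalize",
    "CD3_COMPLEX_GENES",
]

CD3_COMPLEX_GENES = ["CD3D", "CD3E", "CD3G", "CD247"]


@dataclass
class AgreementResult:
    """2x2 agreement between two binary raters."""

    contingency: np.ndarray
    kappa: float
    ci_low: float
    ci_high: float
    label: str

    def __post_init__(self):
        if not -1.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [-1, 1]")
        if not self.ci_low <= self.kappa <= self.ci_high:
            raise ValueError("CI must bracket kappa")


@dataclass
class MarkerDichotomy:
    """Dichotomization rule for a percentage-valued marker."""

    marker_name: str
    threshold: float = 0.0
    rule: str = "fixed"  # 'fixed' or 'median'

    def __post_init__(self):
        if self.rule not in ("fixed", "median"):
            raise ValueError("rule must be 'fixed' or 'median'")
        if self.rule == "fixed" and not 0.0 <= self.threshold <= 100.0:
            raise ValueError("threshold must be a percentage in [0, 100]")


def landis_koch_label(kappa: float) -> str:
    """Qualitative agreement band of a kappa value (Landis–Koch)."""
    eps = 1e-9  # keep exact band edges (0.2, 0.4, ...) in the lower band
    if kappa <= eps:
        return "poor"
    if kappa <= 0.2 + eps:
        return "slight"
    if kappa <= 0.4 + eps:
        return "fair"
    if kappa <= 0.6 + eps:
        return "moderate"
    if kappa <= 0.8 + eps:
        return "substantial"
    return "almost perfect"


def cohen_kappa(a, b, confidence: float = 0.95) -> AgreementResult:
    """Chance-corrected agreement between two binary label vectors.

    kappa = (p_o - p_e) / (1 - p_e) with the large-sample standard error
    sqrt(p_o (1 - p_o)) / ((1 - p_e) sqrt(n)); the normal CI is truncated to
    [-1, 1]. Symmetric in its arguments.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length label vectors of length >= 2")
    n = a.size
    table = np.array([[np.sum(a & b), np.sum(a & ~b)],
                      [np.sum(~a & b), np.sum(~a & ~b)]], dtype=float)
    po = (table[0, 0] + table[1, 1]) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    pe = row @ col
    if pe >= 1.0:
        raise ValueError("expected agreement is 1 (both raters constant and equal); "
                         "kappa undefined")
    kappa = (po - pe) / (1 - pe)
    se = np.sqrt(po * (1 - po)) / ((1 - pe) * np.sqrt(n))
    zcrit = sps.norm.ppf(0.5 + confidence / 2)
    lo = max(-1.0, kappa - zcrit * se)
    hi = min(1.0, kappa + zcrit * se)
    kappa = float(np.clip(kappa, -1.0, 1.0))
    return AgreementResult(table.astype(int), kappa, min(lo, kappa), max(hi, kappa),
                           landis_koch_label(kappa))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2x2 table of nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("a table margin is zero; association undefined")
    return float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])


def _kw_statistic(values: np.ndarray, groups: np.ndarray) -> float:
    """Tie-corrected Kruskal–Wallis H."""
    ranks = sps.rankdata(values)
    n = values.size
    h = 0.0
    for g in np.unique(groups):
        r = ranks[groups == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n) if n > 1 else 1.0
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(values, groups, exact: bool = False) -> tuple[float, float]:
    """Kruskal–Wallis H and p-value across >= 2 groups.

    The default p is the chi-square approximation with g-1 df. With
    ``exact=True`` (two groups, small n) the p-value is the exact permutation
    tail P(H >= H_obs) over all assignments of the observations to groups.
    All-identical values give (0, 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need >= 2 groups")
    if np.unique(values).size == 1:
        return 0.0, 1.0
    h = _kw_statistic(values, groups)
    if exact:
        if levels.size != 2:
            raise ValueError("exact permutation p implemented for 2 groups only")
        n = values.size
        n1 = int(np.sum(groups == levels[0]))
        idx = np.arange(n)
        count = total = 0
        for chosen in combinations(idx, n1):
            g = np.full(n, levels[1], dtype=object)
            g[list(chosen)] = levels[0]
            total += 1
            if _kw_statistic(values, g) >= h - 1e-12:
                count += 1
        return float(h), count / total
    p = float(sps.chi2.sf(h, levels.size - 1))
    return float(h), p


def spearman_ci(x, y, confidence: float = 0.95,
                strong_limit: float = 0.6) -> tuple[float, float, float, bool]:
    """Spearman rank correlation with a Fisher-z CI on the ranks.

    Returns (r_s, ci_low, ci_high, strong) where ``strong`` flags a lower
    confidence limit above ``strong_limit`` (the strong-correlation rule).
    Needs n >= 4 finite observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    r = float(sps.spearmanr(x, y).statistic)
    n = x.size
    zcrit = sps.norm.ppf(0.5 + confidence / 2)
    rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(rr)
    half = zcrit / np.sqrt(n - 3)
    lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return r, lo, hi, lo > strong_limit


def cd3_pca_score(expr: ExpressionMatrix, cd3_genes=CD3_COMPLEX_GENES) -> pd.Series:
    """First principal component of the CD3-complex genes as a CD3 surrogate.

    Gene rows are z-standardized, the first PC of the samples computed, and
    the sign fixed so the score correlates positively with the mean of the
    genes. At least two of the genes must be present.
    """
    present = [g for g in cd3_genes if g in expr.data.index]
    if len(present) < 2:
        raise ValueError(f"need >= 2 of {list(cd3_genes)} present, found {present}")
    rows = expr.data.loc[present]
    mu = rows.mean(axis=1)
    sd = rows.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = rows.sub(mu, axis=0).div(sd, axis=0).fillna(0.0).to_numpy()
    # SVD of the genes x samples z-matrix: first right singular vector = PC1
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    score = s[0] * vt[0]
    mean_expr = z.mean(axis=0)
    if np.dot(score - score.mean(), mean_expr - mean_expr.mean()) < 0:
        score = -score
    return pd.Series(score, index=expr.data.columns)


def cd45_normalize(expr: ExpressionMatrix, gene: str,
                   cd45_gene: str = "PTPRC", mode: str = "log2_difference") -> pd.Series:
    """Normalize an immune gene to CD45 (PTPRC) per sample.

    Default is the difference on the log2 scale; ``mode='linear_ratio'``
    returns 2**gene / 2**CD45 instead.
    """
    for g in (gene, cd45_gene):
        if g not in expr.data.index:
            raise ValueError(f"gene {g!r} absent from matrix")
    diff = expr.data.loc[gene] - expr.data.loc[cd45_gene]
    if mode == "log2_difference":
        return diff
    if mode == "linear_ratio":
        return np.exp2(diff)
    raise ValueError("mode must be 'log2_difference' or 'linear_ratio'")


def dichotomize_marker(values, rule: MarkerDichotomy) -> np.ndarray:
    """Dichotomize percentage marker values (True = high).

    Fixed rule: high iff value > threshold; median rule: threshold is the
    cohort median (strict comparison in both cases, so an all-equal cohort
    under the median rule is all low).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty marker vector")
    if ((values < 0) | (values > 100)).any():
        raise ValueError("marker values must be percentages in [0, 100]")
    thr = float(np.median(values)) if rule.rule == "median" else rule.threshold
    return values > thr
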