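"""Reduction of a large signature to a small logistic classifier.

The procedure, applied to a cohort with known signature status:

1. **Screen** every panel gene with a two-group Kruskal–Wallis test,
   keeping genes with p < alpha whose shift direction (median in positives
   minus median in negatives) matches the panel's expected modulation.
2. **Prune redundancy**: compute pairwise Spearman correlations among the
   screened genes; a pair is "strong" when the lower 95% confidence limit
   of r_s exceeds 0.6. Iteratively retain the gene involved in the most
   strong pairs (ties broken by a relevance ranking, default ascending KW
   p, then gene id) and drop its strongly correlated partners.
3. **Bonferroni**: keep genes with KW p < alpha / m, m = genes entering
   this stage.
4. **All-subset logistic regression**: fit every nonempty subset up to
   ``max_size`` on within-cohort z-scores, score each by the c-statistic of
   the fitted probabilities, and pick the most parsimonious subset within
   0.005 of the best c.
5. **Optimal cutoff**: dichotomize the winning linear predictor at the
   threshold maximizing percent agreement with the original status.

Stage containment holds by construction: final genes are a subset of the
survivors of every earlier stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .classifier import apply_reduced
from .datatypes import ExpressionMatrix, GenePanel, ReducedSignature, SignatureStatus
from .stats import AgreementResult, cohen_kappa, kruskal_wallis, spearman_ci

logger = logging.getLogger("decif")

__all__ = [
    "ReductionConfig",
    "ReductionTrace",
    "kw_screen",
    "strong_correlation_pairs",
    "prune_redundant",
    "bonferroni_select",
    "all_subset_logistic",
    "optimal_cutoff",
    "reduce_signature",
    "SignatureReducer",
]

#: absolute coefficient bound on z-scored inputs; a fitted log-odds slope
#: beyond this is de facto separation (odds ratio > e^10 per SD)
COEF_CLIP = 10.0


@dataclass
class ReductionConfig:
    alpha: float = 0.05
    confidence: float = 0.95
    strong_limit: float = 0.6
    max_size: int = 8
    max_candidates: int = 12
    c_tolerance: float = 0.005
    relevance_rank: list | None = None  # explicit priority order; default = ascending KW p


@dataclass
class ReductionTrace:
    """Full record of every reduction-stage decision."""

    stage1_genes: list = field(default_factory=list)
    stage1_pvalues: dict = field(default_factory=dict)
    strong_pairs: list = field(default_factory=list)
    pruned_genes: dict = field(default_factory=dict)  # gene -> reason
    post_prune_genes: list = field(default_factory=list)
    bonferroni_survivors: list = field(default_factory=list)
    candidate_subsets: list = field(default_factory=list)  # (genes, c, flagged)
    final: ReducedSignature | None = None
    agreement: AgreementResult | None = None

    def check_containment(self) -> bool:
        s1, bf = set(self.stage1_genes), set(self.bonferroni_survivors)
        fin = set(self.final.genes) if self.final else set()
        return fin <= bf <= set(self.post_prune_genes) <= s1


def kw_screen(expr: ExpressionMatrix, panel: GenePanel, status: SignatureStatus,
              alpha: float = 0.05) -> tuple[list, dict]:
    """Direction-filtered Kruskal–Wallis screen of panel genes.

    A gene passes iff KW p < alpha and the sign of (median in positives -
    median in negatives) equals the panel's expected direction. Returns the
    passing genes and the p-values of every tested gene.
    """
    pos = status.status
    if pos.all() or (~pos).all():
        raise ValueError("both status classes must be nonempty")
    present = [g for g in panel.genes if g in expr.data.index]
    pvals: dict = {}
    passing = []
    pos_samples = pos[pos].index
    neg_samples = pos[~pos].index
    for g in present:
        row = expr.data.loc[g]
        a = row[pos_samples].dropna().to_numpy()
        b = row[neg_samples].dropna().to_numpy()
        vals = np.concatenate([a, b])
        grp = np.r_[np.zeros(a.size), np.ones(b.size)]
        _, p = kruskal_wallis(vals, grp)
        pvals[g] = p
        direction = np.sign(np.median(a) - np.median(b))
        if p < alpha and direction == panel.directions[g]:
            passing.append(g)
    return passing, pvals


def strong_correlation_pairs(expr: ExpressionMatrix, genes: list,
                             confidence: float = 0.95,
                             strong_limit: float = 0.6) -> list:
    """All gene pairs whose Spearman lower confidence limit exceeds the cutoff.

    Returns tuples (gene_i, gene_j, r_s, ci_low, ci_high).
    """
    out = []
    for gi, gj in combinations(genes, 2):
        x = expr.data.loc[gi].to_numpy()
        y = expr.data.loc[gj].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        r, lo, hi, strong = spearman_ci(x[ok], y[ok], confidence, strong_limit)
        if strong:
            out.append((gi, gj, r, lo, hi))
    return out


def prune_redundant(genes: list, strong_pairs: list,
                    relevance_rank: list | None = None) -> tuple[list, dict]:
    """Collapse strongly correlated gene groups to single representatives.

    While strong pairs remain, the gene appearing in the most strong pairs
    is retained and every gene strongly paired with it dropped; ties are
    broken by the relevance ranking (a total order, earlier = more relevant)
    and then lexicographic gene id. Deterministic. Returns the retained
    gene list (original order) and a {dropped gene: reason} map.
    """
    genes = list(genes)
    rank = {g: i for i, g in enumerate(relevance_rank)} if relevance_rank else {}
    pairs = {frozenset((a, b)) for a, b, *_ in strong_pairs
             if a in genes and b in genes and a != b}
    alive = set(genes)
    dropped: dict = {}
    while True:
        live_pairs = [p for p in pairs if p <= alive]
        if not live_pairs:
            break
        counts: dict = {}
        for p in live_pairs:
            for g in p:
                counts[g] = counts.get(g, 0) + 1
        keeper = min(counts, key=lambda g: (-counts[g], rank.get(g, len(rank)), str(g)))
        partners = {g for p in live_pairs if keeper in p for g in p} - {keeper}
        for g in partners:
            alive.discard(g)
            dropped[g] = f"strongly correlated with retained gene {keeper}"
        pairs = {p for p in pairs if p <= alive and keeper not in p}
    return [g for g in genes if g in alive], dropped


def bonferroni_select(genes: list, p_values: dict, alpha: float = 0.05,
                      m: int | None = None) -> list:
    """Keep genes with p < alpha / m (default m = number of genes tested)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = len(genes) if m is None else m
    if m < len(genes):
        raise ValueError("Bonferroni denominator smaller than the number tested")
    thr = alpha / m
    logger.info("Bonferroni: threshold %.3g (alpha=%g, m=%d)", thr, alpha, m)
    return [g for g in genes if p_values[g] < thr]


def _zscore_rows(expr: ExpressionMatrix, genes: list) -> pd.DataFrame:
    rows = expr.data.loc[genes]
    mu = rows.mean(axis=1)
    sd = rows.std(axis=1, ddof=1).replace(0.0, np.nan)
    return rows.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Unpenalized logistic fit with coefficient clipping on separation."""
    model = LogisticRegression(C=np.inf, solver="newton-cholesky", max_iter=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation raises solver warnings
        model.fit(X, y)
    coef = model.coef_[0].copy()
    intercept = float(model.intercept_[0])
    flagged = bool(np.any(np.abs(coef) > COEF_CLIP) or abs(intercept) > COEF_CLIP)
    if flagged:
        coef = np.clip(coef, -COEF_CLIP, COEF_CLIP)
        intercept = float(np.clip(intercept, -COEF_CLIP, COEF_CLIP))
    return intercept, coef, flagged


def all_subset_logistic(expr: ExpressionMatrix, candidate_genes: list,
                        status: SignatureStatus, max_size: int = 8,
                        c_tolerance: float = 0.005,
                        signature_name: str = "reduced"
                        ) -> tuple[list, ReducedSignature]:
    """Exhaustive subset search over logistic models on gene z-scores.

    Every nonempty subset of the candidates up to ``max_size`` is fitted and
    scored by the c-statistic (area under the ROC of fitted probabilities
    against status). The winner is the subset with the fewest genes among
    those within ``c_tolerance`` of the maximum c (ties: higher c, then
    lexicographic gene tuple). The returned signature's cutoff is 0 and is
    meant to be replaced by :func:`optimal_cutoff`.
    """
    if len(candidate_genes) > 20:
        raise ValueError("exhaustive subset search limited to <= 20 candidates")
    if not candidate_genes:
        raise ValueError("no candidate genes")
    y = status.status.reindex(expr.data.columns).to_numpy()
    if y.all() or (~y).all():
        raise ValueError("both status classes must be nonempty")
    Z = _zscore_rows(expr, candidate_genes)
    records = []
    for size in range(1, min(max_size, len(candidate_genes)) + 1):
        for genes in combinations(candidate_genes, size):
            X = Z.loc[list(genes)].to_numpy().T
            intercept, coef, flagged = _fit_logistic(X, y)
            lp = intercept + X @ coef
            prob = 1.0 / (1.0 + np.exp(-lp))
            c = float(roc_auc_score(y, prob))
            records.append({"genes": list(genes), "c": c, "flagged": flagged,
                            "intercept": intercept, "coef": coef})
            if flagged:
                logger.info("subset %s: separation flagged, coefficients clipped", genes)
    best_c = max(r["c"] for r in records)
    admissible = [r for r in records if r["c"] >= best_c - c_tolerance]
    winner = min(admissible,
                 key=lambda r: (len(r["genes"]), -r["c"], tuple(map(str, r["genes"]))))
    sig = ReducedSignature(
        signature_name=signature_name,
        genes=winner["genes"],
        intercept=winner["intercept"],
        coefficients=pd.Series(winner["coef"], index=winner["genes"]),
        cutoff=0.0,
        training_provenance=f"all-subset logistic, c={winner['c']:.4f}",
    )
    subsets = [(r["genes"], r["c"], r["flagged"]) for r in records]
    return subsets, sig


def optimal_cutoff(scores, status) -> float:
    """Threshold maximizing agreement between (score >= cutoff) and status.

    Candidates are the midpoints of consecutive sorted unique scores plus
    the two boundary thresholds (everything positive / nothing positive);
    the lowest maximizing cutoff is returned.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status).astype(bool)
    if scores.size != status.size or scores.size == 0:
        raise ValueError("scores and status must align and be nonempty")
    uniq = np.unique(scores)
    if uniq.size == 1:
        raise ValueError("constant scores: cutoff undefined")
    candidates = np.r_[uniq[0], (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1] + 1.0]
    best_cut, best_agree = None, -1.0
    for cut in candidates:
        agree = float(np.mean((scores >= cut) == status))
        if agree > best_agree + 1e-12:
            best_agree, best_cut = agree, float(cut)
    return best_cut


def reduce_signature(expr: ExpressionMatrix, panel: GenePanel,
                     status: SignatureStatus,
                     config: ReductionConfig | None = None
                     ) -> tuple[ReducedSignature, ReductionTrace]:
    """Run the full five-stage reduction and report the trace."""
    cfg = config or ReductionConfig()
    trace = ReductionTrace()

    trace.stage1_genes, trace.stage1_pvalues = kw_screen(expr, panel, status, cfg.alpha)
    if not trace.stage1_genes:
        raise ValueError("no gene passed the direction-filtered KW screen")

    trace.strong_pairs = strong_correlation_pairs(
        expr, trace.stage1_genes, cfg.confidence, cfg.strong_limit)
    relevance = cfg.relevance_rank or sorted(
        trace.stage1_genes, key=lambda g: (trace.stage1_pvalues[g], str(g)))
    trace.post_prune_genes, trace.pruned_genes = prune_redundant(
        trace.stage1_genes, trace.strong_pairs, relevance)

    trace.bonferroni_survivors = bonferroni_select(
        trace.post_prune_genes, trace.stage1_pvalues, cfg.alpha,
        m=len(trace.post_prune_genes))
    if not trace.bonferroni_survivors:
        raise ValueError("no gene survived the Bonferroni selection")
    candidates = trace.bonferroni_survivors
    if len(candidates) > cfg.max_candidates:
        ordered = sorted(candidates, key=lambda g: (trace.stage1_pvalues[g], str(g)))
        candidates = [g for g in trace.bonferroni_survivors
                      if g in set(ordered[: cfg.max_candidates])]
        logger.warning("capping subset-search candidates at %d (of %d) by KW p",
                       cfg.max_candidates, len(trace.bonferroni_survivors))

    trace.candidate_subsets, sig = all_subset_logistic(
        expr, candidates, status, cfg.max_size, cfg.c_tolerance,
        signature_name=f"{panel.name}-reduced")

    interim = apply_reduced(expr, sig)
    sig.cutoff = optimal_cutoff(interim.score.to_numpy(),
                                status.status.reindex(interim.score.index).to_numpy())
    trace.final = sig

    final_status = apply_reduced(expr, sig)
    trace.agreement = cohen_kappa(
        status.status.reindex(final_status.status.index).to_numpy(),
        final_status.status.to_numpy(), cfg.confidence)
    logger.info("reduced %s: %d gene(s), kappa %.3f (%s)", panel.name,
                len(sig.genes), trace.agreement.kappa, trace.agreement.label)
    return sig, trace


class SignatureReducer(BaseEstimator):
    """scikit-learn style front end to :func:`reduce_signature`.

    ``fit(X, y)`` takes samples x genes data (gene-id columns) and the
    original binary status; fitted attributes are ``signature_`` and
    ``trace_``. ``predict`` applies the reduced signature to new cohorts.
    """

    def __init__(self, panel: GenePanel = None, alpha: float = 0.05,
                 confidence: float = 0.95, strong_limit: float = 0.6,
                 max_size: int = 8, max_candidates: int = 12,
                 c_tolerance: float = 0.005, relevance_rank: list | None = None):
        self.panel = panel
        self.alpha = alpha
        self.confidence = confidence
        self.strong_limit = strong_limit
        self.max_size = max_size
        self.max_candidates = max_candidates
        self.c_tolerance = c_tolerance
        self.relevance_rank = relevance_rank

    def fit(self, X, y):
        if self.panel is None:
            raise ValueError("SignatureReducer requires a gene panel")
        X = pd.DataFrame(X)
        expr = ExpressionMatrix(X.T, "array")
        status = SignatureStatus(self.panel.name,
                                 pd.Series(np.asarray(y, dtype=bool), index=X.index),
                                 pd.Series(0.0, index=X.index))
        cfg = ReductionConfig(self.alpha, self.confidence, self.strong_limit,
                              self.max_size, self.max_candidates,
                              self.c_tolerance, self.relevance_rank)
        self.signature_, self.trace_ = reduce_signature(expr, self.panel, status, cfg)
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        expr = ExpressionMatrix(X.T, "array")
        return apply_reduced(expr, self.signature_).status.to_numpy()
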