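"""Large-average-submatrix (LAS) biclustering and the ECM3 sample call.

The LAS score of a k-gene x l-sample submatrix of a standardized m x n
matrix with entry average tau is

    S(k, l, tau) = -log Phi(-tau * sqrt(k*l)) - log C(m, k) - log C(n, l),

the log tail probability of the submatrix sum under the standard normal
null, Bonferroni-penalised by the number of submatrices of that size.
Each search restart runs in two phases. A warm-up alternation at a
randomly drawn fixed size (k genes, l samples) maximizes the submatrix
mean, concentrating the restart on a tight high-mean seed; the sizes are
then released and the alternation maximizes the score itself — for a
fixed sample set the best gene subset of each size k is the top-k genes
by submatrix row mean, so a sort and a prefix scan suffice per half-step.

ECM3-positive samples are the members of the top-scoring positive-average
bicluster found on the matrix restricted to the ECM gene panel.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .datatypes import Bicluster, ExpressionMatrix, GenePanel, SignatureStatus

logger = logging.getLogger("decif")

__all__ = [
    "standardize",
    "las_score",
    "las_search",
    "call_ecm3",
    "LASBiclusterer",
    "ECM3Classifier",
]


def standardize(expr: ExpressionMatrix, panel: GenePanel | None = None) -> ExpressionMatrix:
    """Row-standardize (mean 0, sd 1 per gene), optionally restricted to a panel.

    Panel genes absent from the matrix are logged and skipped; constant rows
    are dropped with a warning. Missing values are mean-imputed (i.e. set to
    z = 0) for scoring only. Idempotent on an already-standardized matrix.
    """
    data = expr.data
    if panel is not None:
        present = [g for g in panel.genes if g in data.index]
        absent = sorted(set(panel.genes) - set(present))
        if absent:
            logger.warning("standardize: %d panel gene(s) absent from platform: %s",
                           len(absent), absent[:10])
        data = data.loc[present]
    if data.shape[1] < 2:
        raise ValueError("standardization needs >= 2 samples")
    mu = data.mean(axis=1, skipna=True)
    sd = data.std(axis=1, ddof=1, skipna=True)
    constant = sd.fillna(0.0) == 0.0
    if constant.any():
        logger.warning("standardize: dropping %d constant gene row(s): %s",
                       int(constant.sum()), list(data.index[constant])[:10])
        data, mu, sd = data.loc[~constant], mu[~constant], sd[~constant]
    if data.shape[0] < 2:
        raise ValueError("fewer than 2 usable genes after standardization")
    z = data.sub(mu, axis=0).div(sd, axis=0)
    return ExpressionMatrix(z.fillna(0.0), expr.platform_tag)


def las_score(k, l, tau, m: int, n: int):
    """LAS log-significance score of a k x l submatrix with mean ``tau``.

    Vectorized over ``k``, ``l`` and ``tau``; numerically stable for
    tau*sqrt(k*l) up to several hundred via the normal log-tail.
    """
    k = np.asarray(k, dtype=float)
    l = np.asarray(l, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if not np.isfinite(tau).all():
        raise ValueError("submatrix mean tau must be finite")
    if np.any(k < 1) or np.any(k > m) or np.any(l < 1) or np.any(l > n):
        raise ValueError("require 1 <= k <= m and 1 <= l <= n")

    def _logcomb(N, r):
        return gammaln(N + 1) - gammaln(r + 1) - gammaln(N - r + 1)

    # -log Phi(-x) = -log sf(x)
    tail = -norm.logsf(tau * np.sqrt(k * l))
    out = tail - _logcomb(float(m), k) - _logcomb(float(n), l)
    return out if out.ndim else float(out)


def _best_subset_for(Z: np.ndarray, axis_means: np.ndarray, fixed_count: int,
                     m: int, n: int, axis: int) -> tuple[np.ndarray, float]:
    """Best prefix of ``axis_means`` (sorted desc) for a fixed other-side count.

    Returns the chosen index array and the score. ``axis`` = 0 selects genes
    (k varies, l = fixed_count) and 1 selects samples.
    """
    order = np.argsort(-axis_means, kind="stable")
    cum = np.cumsum(axis_means[order])
    sizes = np.arange(1, axis_means.size + 1)
    taus = cum / sizes
    if axis == 0:
        scores = las_score(sizes, fixed_count, taus, m, n)
    else:
        scores = las_score(fixed_count, sizes, taus, m, n)
    best = int(np.argmax(scores))
    return np.sort(order[: best + 1]), float(scores[best])


def _fixed_size_phase(Z: np.ndarray, k: int, l: int, rng, max_iter: int = 30
                      ) -> np.ndarray:
    """Tau-maximizing alternation at fixed submatrix size (k genes, l samples).

    Starting from a random sample subset of size l, alternately take the
    top-k genes by submatrix row mean and the top-l samples by submatrix
    column mean until the sets repeat. Returns the sample subset, which
    seeds the size-adaptive phase: the adaptive prefix scan cannot climb
    towards a small dense block from a diffuse random start (the size
    penalty dominates a diluted signal), but it refines a tight high-mean
    seed reliably.
    """
    n = Z.shape[1]
    cols = np.sort(rng.choice(n, size=l, replace=False))
    prev = None
    for _ in range(max_iter):
        rows = np.argsort(-Z[:, cols].mean(axis=1), kind="stable")[:k]
        cols = np.argsort(-Z[rows, :].mean(axis=0), kind="stable")[:l]
        key = (rows.tobytes(), cols.tobytes())
        if key == prev:
            break
        prev = key
    return np.sort(cols)


def _alternate_from(Z: np.ndarray, cols: np.ndarray, max_iter: int = 100
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    m, n = Z.shape
    rows = np.arange(m)
    prev = None
    score = -np.inf
    for _ in range(max_iter):
        rows, score = _best_subset_for(Z, Z[:, cols].mean(axis=1), cols.size, m, n, axis=0)
        cols, score = _best_subset_for(Z, Z[rows, :].mean(axis=0), rows.size, m, n, axis=1)
        key = (rows.tobytes(), cols.tobytes())
        if key == prev:
            break
        prev = key
    return rows, cols, score


def _exhaustive_search(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    m, n = Z.shape
    if m > 12 or n > 12:
        raise ValueError("exhaustive LAS search is limited to matrices up to 12 x 12")
    best = (None, None, -np.inf)
    for k in range(1, m + 1):
        for rows in combinations(range(m), k):
            sub = Z[list(rows), :]
            col_means = sub.mean(axis=0)
            for l in range(1, n + 1):
                for cols in combinations(range(n), l):
                    tau = col_means[list(cols)].mean()
                    s = las_score(k, l, tau, m, n)
                    if s > best[2]:
                        best = (np.array(rows), np.array(cols), float(s))
    return best


def las_search(std_expr: ExpressionMatrix, n_restarts: int = 1000,
               seed: int | None = None, method: str = "alternating",
               require_positive: bool = False) -> Bicluster:
    """Search for the top-scoring bicluster of a standardized matrix.

    ``method='alternating'`` runs ``n_restarts`` random restarts of the
    alternating prefix maximization; ``method='exhaustive'`` enumerates all
    row-subset x column-subset pairs (small matrices only). With
    ``require_positive`` the best bicluster with a positive submatrix
    average is returned instead of the overall optimum (None if none found).
    Deterministic for a fixed seed.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    Z = std_expr.data.to_numpy()
    m, n = Z.shape

    if method == "exhaustive":
        rows, cols, score = _exhaustive_search(Z)
        if require_positive and Z[np.ix_(rows, cols)].mean() <= 0:
            # rescan keeping only positive-average optima
            best = (None, None, -np.inf)
            for k in range(1, m + 1):
                for r in combinations(range(m), k):
                    sub = Z[list(r), :]
                    cm = sub.mean(axis=0)
                    for l in range(1, n + 1):
                        for c in combinations(range(n), l):
                            tau = cm[list(c)].mean()
                            if tau <= 0:
                                continue
                            s = las_score(k, l, tau, m, n)
                            if s > best[2]:
                                best = (np.array(r), np.array(c), float(s))
            if best[0] is None:
                return None
            rows, cols, score = best
    elif method == "alternating":
        rng = np.random.default_rng(seed)
        best = (None, None, -np.inf)
        best_pos = (None, None, -np.inf)
        for _ in range(n_restarts):
            # seed size drawn log-uniformly up to half the matrix per side
            k0 = int(np.exp(rng.uniform(np.log(1.0), np.log(max(m / 2, 2.0)))))
            l0 = int(np.exp(rng.uniform(np.log(1.0), np.log(max(n / 2, 2.0)))))
            cols0 = _fixed_size_phase(Z, max(k0, 1), max(l0, 1), rng)
            rows, cols, score = _alternate_from(Z, cols0)
            if score > best[2]:
                best = (rows, cols, score)
            if score > best_pos[2] and Z[np.ix_(rows, cols)].mean() > 0:
                best_pos = (rows, cols, score)
        rows, cols, score = best_pos if require_positive else best
        if rows is None:
            return None
    else:
        raise ValueError(f"unknown method {method!r}")

    genes = std_expr.data.index[rows]
    samples = std_expr.data.columns[cols]
    avg = float(Z[np.ix_(rows, cols)].mean())
    return Bicluster(frozenset(genes), frozenset(samples), avg, score)


def call_ecm3(expr: ExpressionMatrix, ecm_panel: GenePanel,
              n_restarts: int = 1000, seed: int | None = None,
              panel_scope: bool = True) -> tuple[list[SignatureStatus], Bicluster | None]:
    """ECM3 status for every sample via LAS on the ECM panel submatrix.

    Samples belonging to the top positive-average bicluster are called
    positive; the per-sample score is the mean standardized expression over
    the bicluster's gene set. ``panel_scope=False`` runs the search on the
    full matrix instead of the ECM-panel submatrix.
    """
    std = standardize(expr, ecm_panel if panel_scope else None)
    bic = las_search(std, n_restarts=n_restarts, seed=seed, require_positive=True)
    samples = pd.Index(expr.sample_ids)
    if bic is None:
        logger.warning("call_ecm3: no positive-average bicluster found; all-negative call")
        status = pd.Series(False, index=samples)
        score = pd.Series(0.0, index=samples)
        return [SignatureStatus("ECM3", status, score)], None
    gene_rows = std.data.loc[sorted(bic.gene_set)]
    score = gene_rows.mean(axis=0).reindex(samples)
    status = pd.Series(samples.isin(bic.sample_set), index=samples)
    return [SignatureStatus("ECM3", status, score)], bic


class LASBiclusterer(BaseEstimator):
    """scikit-learn style wrapper around the LAS search.

    ``fit`` expects ``X`` of shape (n_samples, n_features) following the
    scikit-learn convention; rows of the internal genes x samples matrix are
    the features. Fitted attributes: ``rows_`` (feature/gene mask),
    ``columns_`` (sample mask), ``avg_``, ``score_``.
    """

    def __init__(self, n_restarts: int = 1000, random_state: int | None = None,
                 method: str = "alternating", require_positive: bool = False):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.method = method
        self.require_positive = require_positive

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_samples, n_features)")
        df = pd.DataFrame(X.T)  # features (genes) in rows
        expr = ExpressionMatrix(df, "array")
        bic = las_search(expr, n_restarts=self.n_restarts, seed=self.random_state,
                         method=self.method, require_positive=self.require_positive)
        n_feat, n_samp = df.shape
        self.rows_ = np.zeros(n_feat, dtype=bool)
        self.columns_ = np.zeros(n_samp, dtype=bool)
        if bic is not None:
            self.rows_[[int(g) for g in bic.gene_set]] = True
            self.columns_[[int(s) for s in bic.sample_set]] = True
            self.avg_ = bic.avg
            self.score_ = bic.score
        else:
            self.avg_ = np.nan
            self.score_ = -np.inf
        return self


class ECM3Classifier(BaseEstimator):
    """Transductive ECM3 caller: LAS biclustering over an ECM gene panel.

    Parameters follow scikit-learn conventions; ``fit`` takes a genes x
    samples :class:`ExpressionMatrix` (or a samples x genes DataFrame with
    gene-id columns). Fitted attributes: ``labels_`` (bool per sample),
    ``scores_`` (bicluster-mean z per sample), ``bicluster_``.
    """

    def __init__(self, panel: GenePanel = None, n_restarts: int = 1000,
                 random_state: int | None = None, panel_scope: bool = True):
        self.panel = panel
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.panel_scope = panel_scope

    def _as_expression(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        df = pd.DataFrame(X)
        return ExpressionMatrix(df.T, "array")  # samples x genes -> genes x samples

    def fit(self, X, y=None):
        if self.panel is None:
            raise ValueError("ECM3Classifier requires a gene panel")
        expr = self._as_expression(X)
        statuses, bic = call_ecm3(expr, self.panel, n_restarts=self.n_restarts,
                                  seed=self.random_state, panel_scope=self.panel_scope)
        st = statuses[0]
        self.status_ = st
        self.labels_ = st.status.to_numpy()
        self.scores_ = st.score.to_numpy()
        self.bicluster_ = bic
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
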