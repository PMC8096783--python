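"""IFN metagene scoring and median dichotomization.

The metagene score of a sample is the mean over the panel genes of the
direction-signed within-cohort z-score; samples strictly above the cohort
median (50th percentile) are IFN-positive. Ties at the median go to the
negative class, so the positive fraction never exceeds 50%.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .biclustering import standardize
from .datatypes import ExpressionMatrix, GenePanel, SignatureStatus

logger = logging.getLogger("decif")

__all__ = ["metagene_score", "dichotomize_ifn", "IFNClassifier"]


def metagene_score(expr: ExpressionMatrix, panel: GenePanel) -> pd.Series:
    """Per-sample metagene score: mean of direction-signed gene z-scores."""
    present = [g for g in panel.genes if g in expr.data.index]
    missing = sorted(set(panel.genes) - set(present))
    if len(present) < 2:
        if len(present) == 1:
            logger.warning("metagene %s: single-gene panel (missing: %s); "
                           "score is that gene's z-score", panel.name, missing)
        else:
            raise ValueError(
                f"metagene {panel.name}: fewer than 2 panel genes present; missing {missing}")
    if missing:
        logger.warning("metagene %s: %d panel gene(s) absent: %s",
                       panel.name, len(missing), missing[:10])
    if len(present) == 1:
        g = present[0]
        row = expr.data.loc[g]
        z = (row - row.mean()) / row.std(ddof=1)
        return float(panel.directions[g]) * z.fillna(0.0)
    std = standardize(expr.subset_genes(present))
    signed = std.data.mul(panel.directions.reindex(std.data.index), axis=0)
    return signed.mean(axis=0)


def dichotomize_ifn(scores: pd.Series, signature_name: str = "IFN") -> SignatureStatus:
    """Call positive the samples with score strictly above the cohort median."""
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 2:
        raise ValueError("dichotomization needs >= 2 samples")
    if scores.nunique() == 1:
        logger.warning("all metagene scores identical; calling all samples negative")
        return SignatureStatus(signature_name,
                               pd.Series(False, index=scores.index), scores)
    cutoff = float(np.median(scores.to_numpy()))
    return SignatureStatus(signature_name, scores > cutoff, scores)


class IFNClassifier(BaseEstimator):
    """Metagene scorer + cohort-median dichotomizer, scikit-learn style.

    ``fit`` learns per-gene standardization parameters and the median cutoff
    from the cohort; ``transform`` returns metagene scores and ``predict``
    binary status for new samples on the same platform. Fitted attributes:
    ``cutoff_``, ``gene_means_``, ``gene_sds_``, ``labels_``, ``scores_``.
    """

    def __init__(self, panel: GenePanel = None):
        self.panel = panel

    def _as_expression(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        return ExpressionMatrix(pd.DataFrame(X).T, "array")

    def fit(self, X, y=None):
        if self.panel is None:
            raise ValueError("IFNClassifier requires a gene panel")
        expr = self._as_expression(X)
        present = [g for g in self.panel.genes if g in expr.data.index]
        rows = expr.data.loc[present]
        self.gene_means_ = rows.mean(axis=1)
        self.gene_sds_ = rows.std(axis=1, ddof=1).replace(0.0, np.nan)
        scores = metagene_score(expr, self.panel)
        self.scores_ = scores.to_numpy()
        status = dichotomize_ifn(scores, self.panel.name)
        self.cutoff_ = float(np.median(scores.to_numpy()))
        self.labels_ = status.status.to_numpy()
        self.status_ = status
        return self

    def transform(self, X):
        expr = self._as_expression(X)
        genes = self.gene_means_.index
        z = (expr.data.loc[genes].sub(self.gene_means_, axis=0)
             .div(self.gene_sds_, axis=0).fillna(0.0))
        signed = z.mul(self.panel.directions.reindex(genes), axis=0)
        return signed.mean(axis=0).to_numpy()

    def predict(self, X):
        return self.transform(X) > self.cutoff_

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
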