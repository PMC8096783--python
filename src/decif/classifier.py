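"""The joint ECM3/IFN variable, the dichotomous dECIF variable, and the
application of reduced logistic signatures.

dECIF splits the four joint categories into the high-risk ECM3+/IFN-
class versus "other" (every combination that is not ECM3+/IFN-).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .datatypes import ExpressionMatrix, ReducedSignature, SignatureStatus

__all__ = [
    "JOINT_CATEGORIES",
    "HIGH_RISK",
    "OTHER",
    "assign_decif",
    "apply_reduced",
    "ReducedSignatureClassifier",
]

HIGH_RISK = "ECM3+/IFN-"
OTHER = "other"
JOINT_CATEGORIES = ["ECM3+/IFN-", "ECM3+/IFN+", "ECM3-/IFN-", "ECM3-/IFN+"]


def assign_decif(ecm3: SignatureStatus, ifn: SignatureStatus) -> pd.DataFrame:
    """Combine ECM3 and IFN status into the joint and dichotomous variables.

    Returns a DataFrame indexed by sample id with columns ``joint`` (one of
    the four ECM3±/IFN± categories) and ``dichotomous`` (ECM3+/IFN- vs
    "other"). Pure, deterministic 2x2 mapping; both inputs must cover the
    same sample set.
    """
    a, b = set(ecm3.sample_ids), set(ifn.sample_ids)
    if a != b:
        raise ValueError(
            f"sample sets differ; only-ECM3: {sorted(a - b)[:10]}, "
            f"only-IFN: {sorted(b - a)[:10]}")
    ifn_status = ifn.status.reindex(ecm3.status.index)
    joint = np.where(
        ecm3.status, np.where(ifn_status, "ECM3+/IFN+", "ECM3+/IFN-"),
        np.where(ifn_status, "ECM3-/IFN+", "ECM3-/IFN-"))
    dich = np.where(joint == HIGH_RISK, HIGH_RISK, OTHER)
    return pd.DataFrame({"joint": joint, "dichotomous": dich},
                        index=ecm3.status.index)


def apply_reduced(expr: ExpressionMatrix, sig: ReducedSignature) -> SignatureStatus:
    """Apply a reduced logistic signature to a cohort.

    Gene expression is z-standardized within the cohort, the linear
    predictor intercept + sum(coef * z) computed, and samples with predictor
    >= cutoff called positive. All signature genes must be present.
    """
    missing = [g for g in sig.genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"signature {sig.signature_name}: missing gene(s) {missing}")
    rows = expr.data.loc[sig.genes]
    mu = rows.mean(axis=1)
    sd = rows.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = rows.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    lp = sig.intercept + z.mul(sig.coefficients, axis=0).sum(axis=0)
    return SignatureStatus(sig.signature_name, lp >= sig.cutoff, lp)


class ReducedSignatureClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn wrapper around a fixed :class:`ReducedSignature`.

    ``fit`` learns only the within-cohort gene standardization (the weights
    and cutoff are the signature's); ``decision_function`` is the linear
    predictor and ``predict`` the binary status. X is samples x genes with
    gene-id columns.
    """

    def __init__(self, signature: ReducedSignature = None):
        self.signature = signature

    def fit(self, X, y=None):
        if self.signature is None:
            raise ValueError("a ReducedSignature is required")
        X = pd.DataFrame(X)
        missing = [g for g in self.signature.genes if g not in X.columns]
        if missing:
            raise ValueError(f"missing signature gene column(s): {missing}")
        cols = X[self.signature.genes]
        self.gene_means_ = cols.mean(axis=0)
        sds = cols.std(axis=0, ddof=1)
        self.gene_sds_ = sds.replace(0.0, np.nan)
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X):
        X = pd.DataFrame(X)[self.signature.genes]
        z = (X - self.gene_means_) / self.gene_sds_
        z = z.fillna(0.0)
        lp = self.signature.intercept + z.mul(self.signature.coefficients, axis=1).sum(axis=1)
        return lp.to_numpy() - self.signature.cutoff

    def predict(self, X):
        return self.decision_function(X) >= 0.0
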