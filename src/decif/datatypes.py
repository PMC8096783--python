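"""Core in-memory containers shared across the pipeline.

Expression is always log2-scale, genes in rows and samples in columns;
the pipeline never rescales it (preprocessing is upstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GenePanel",
    "SignatureStatus",
    "ReducedSignature",
    "Bicluster",
]


class ExpressionMatrix:
    """A validated genes x samples matrix of log2 expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, float values.
        NaN marks an explicitly missing measurement.
    platform_tag : str
        Free-text provenance tag (e.g. array platform).
    """

    def __init__(self, data: pd.DataFrame, platform_tag: str = ""):
        data = data.astype(float)
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs >= 2 genes and >= 2 samples, got {data.shape}"
            )
        with np.errstate(invalid="ignore"):
            if np.isinf(data.to_numpy()).any():
                raise ValueError("expression values must be finite or NaN (missing)")
        self.data = data
        self.platform_tag = platform_tag

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Iterable) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], self.platform_tag)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


@dataclass
class GenePanel:
    """A named gene list with the expected modulation direction.

    ``directions`` maps gene id -> +1 (over-expressed in signature-positive
    samples) or -1 (under-expressed).
    """

    name: str
    directions: "pd.Series"

    def __post_init__(self):
        s = pd.Series(self.directions, dtype=int)
        if s.empty:
            raise ValueError("gene panel must be nonempty")
        if s.index.duplicated().any():
            raise ValueError("gene panel has duplicate gene ids")
        if not s.isin([1, -1]).all():
            raise ValueError("panel directions must be +1 or -1")
        self.directions = s

    @property
    def genes(self) -> list:
        return list(self.directions.index)

    def __len__(self) -> int:
        return len(self.directions)


@dataclass
class SignatureStatus:
    """Per-sample binary signature call plus a continuous score.

    ``status`` is a boolean Series (True = positive) and ``score`` a float
    Series, both indexed by sample id.
    """

    signature_name: str
    status: "pd.Series"
    score: "pd.Series"

    def __post_init__(self):
        self.status = pd.Series(self.status, dtype=bool)
        self.score = pd.Series(self.score, dtype=float)
        if not self.status.index.equals(self.score.index):
            raise ValueError("status and score must share the same sample index")
        if self.status.index.duplicated().any():
            raise ValueError("duplicate sample ids in signature status")
        if not np.isfinite(self.score.to_numpy()).all():
            raise ValueError("signature scores must be finite")

    @property
    def sample_ids(self) -> list:
        return list(self.status.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.status.index,
                "status": np.where(self.status.to_numpy(), "positive", "negative"),
                "score": self.score.to_numpy(),
                "signature": self.signature_name,
            }
        )


@dataclass
class ReducedSignature:
    """A small logistic-model signature: genes, weights and a score cutoff.

    The linear predictor is ``intercept + sum_g coef[g] * z_g`` where ``z_g``
    is the within-cohort z-score of gene g; samples with predictor >= cutoff
    are called positive.
    """

    signature_name: str
    genes: list
    intercept: float
    coefficients: "pd.Series"
    cutoff: float
    training_provenance: str = ""

    def __post_init__(self):
        self.coefficients = pd.Series(self.coefficients, dtype=float)
        self.genes = list(self.genes)
        if list(self.coefficients.index) != self.genes:
            self.coefficients = self.coefficients.reindex(self.genes)
        if self.coefficients.isna().any():
            raise ValueError("one coefficient required per gene")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "signature_name": self.signature_name,
                "genes": self.genes,
                "intercept": self.intercept,
                "coefficients": self.coefficients.tolist(),
                "cutoff": self.cutoff,
                "training_provenance": self.training_provenance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReducedSignature":
        d = json.loads(text)
        return cls(
            signature_name=d["signature_name"],
            genes=d["genes"],
            intercept=d["intercept"],
            coefficients=pd.Series(d["coefficients"], index=d["genes"]),
            cutoff=d["cutoff"],
            training_provenance=d.get("training_provenance", ""),
        )


@dataclass
class Bicluster:
    """A gene-set x sample-set submatrix with its average and LAS score."""

    gene_set: frozenset
    sample_set: frozenset
    avg: float
    score: float

    def __post_init__(self):
        self.gene_set = frozenset(self.gene_set)
        self.sample_set = frozenset(self.sample_set)
        if not self.gene_set or not self.sample_set:
            raise ValueError("bicluster gene and sample sets must be nonempty")
        if not np.isfinite(self.score):
            raise ValueError("bicluster score must be finite")
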