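"""Readers and writers for expression matrices, clinical tables, gene panels
and long-format qPCR tables (delimited text), plus the expression/clinical
sample join.

Write -> read round-trips are identity for every table kind. Readers never
silently drop rows: rejected rows are reported in the log.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenePanel

logger = logging.getLogger("decif")

#: accepted spellings for hormone-receptor status, mapped to the canonical +/-
RECEPTOR_ALIASES = {
    "+": "+", "-": "-", "pos": "+", "neg": "-", "positive": "+",
    "negative": "-", "1": "+", "0": "-",
}

PAM50_LEVELS = {"Basal", "Her2", "LumA", "LumB", "Normal"}

REQUIRED_CLINICAL = ["sample_id", "os_time", "os_event"]
OPTIONAL_CLINICAL = ["age", "tumor_size", "er", "pgr", "pam50", "grade"]

#: values treated as an explicitly missing expression measurement
NA_TOKENS = {"", "NA", "NaN", "nan", "null", "None"}


def _sep_for(path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, dialect: str | None = None,
                    platform_tag: str = "") -> ExpressionMatrix:
    """Read a genes x samples matrix from delimited text.

    First column = gene ids, header row = sample ids. Duplicate gene rows are
    collapsed by their mean (logged); duplicate sample ids are rejected.
    Non-numeric cells other than the recognised missing tokens raise a parse
    error with row/column coordinates.
    """
    sep = _sep_for(path, dialect)
    with open(path) as fh:  # pandas mangles duplicate header names; check raw
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dup}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)

    values = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = arr[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() in NA_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at gene {raw.index[i]!r} "
                    f"(row {i + 2}), sample {raw.columns[j]!r} (column {j + 2})"
                ) from None
    df = pd.DataFrame(values, index=raw.index, columns=raw.columns)

    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene id(s) by mean: %s", len(dup), dup)
        df = df.groupby(level=0, sort=False).mean()
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        logger.info("expression matrix %s: %d missing value(s) flagged", path, n_missing)
    return ExpressionMatrix(df, platform_tag=platform_tag)


def write_expression(expr: ExpressionMatrix, path, dialect: str | None = None) -> None:
    expr.data.to_csv(path, sep=_sep_for(path, dialect), index_label="gene_id")


def read_clinical(path, dialect: str | None = None) -> pd.DataFrame:
    """Read and validate a clinical table.

    Required columns: sample_id, os_time (months), os_event ({0,1}). Optional:
    age, tumor_size, er, pgr, pam50, grade. Receptor status accepts the
    aliases in :data:`RECEPTOR_ALIASES`; unknown categories are rejected.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required column(s): {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")

    df = df.copy()
    df["os_time"] = df["os_time"].astype(float)
    if (df["os_time"] < 0).any():
        bad = df.loc[df["os_time"] < 0, "sample_id"].tolist()
        raise ValueError(f"negative os_time for sample(s): {bad}")
    if not df["os_event"].isin([0, 1]).all():
        bad = df.loc[~df["os_event"].isin([0, 1]), "os_event"].unique().tolist()
        raise ValueError(f"os_event must be 0 or 1, got {bad}")
    df["os_event"] = df["os_event"].astype(int)

    for col in ("er", "pgr"):
        if col in df.columns:
            mapped = df[col].astype(str).str.strip().str.lower().map(
                {k.lower(): v for k, v in RECEPTOR_ALIASES.items()})
            unknown = df.loc[mapped.isna() & df[col].notna(), col].unique().tolist()
            if unknown:
                raise ValueError(f"unknown {col} categor(ies): {unknown}")
            df[col] = mapped
    if "pam50" in df.columns:
        unknown = set(df["pam50"].dropna()) - PAM50_LEVELS
        if unknown:
            raise ValueError(f"unknown pam50 categor(ies): {sorted(unknown)}")
    logger.info("clinical table %s: %d record(s) loaded", path, len(df))
    return df


def write_clinical(df: pd.DataFrame, path, dialect: str | None = None) -> None:
    df.to_csv(path, sep=_sep_for(path, dialect), index=False)


def read_panel(path, name: str | None = None, dialect: str | None = None) -> GenePanel:
    """Read a gene panel (columns: gene_id, direction in {+1,-1})."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    if "gene_id" not in df.columns or "direction" not in df.columns:
        raise ValueError("panel file needs columns gene_id and direction")
    s = pd.Series(df["direction"].astype(int).to_numpy(), index=df["gene_id"])
    return GenePanel(name or Path(str(path)).stem, s)


def write_panel(panel: GenePanel, path, dialect: str | None = None) -> None:
    pd.DataFrame({"gene_id": panel.genes,
                  "direction": panel.directions.to_numpy()}
                 ).to_csv(path, sep=_sep_for(path, dialect), index=False)


def read_qpcr(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a long-format qPCR well table.

    Columns: plate_id, sample_id, gene_id, replicate, cq. An empty/NA cq marks
    an undetermined well. sample_id values 'CALIBRATOR' and 'BLANK' denote the
    control wells.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    need = ["plate_id", "sample_id", "gene_id", "replicate", "cq"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing column(s): {missing}")
    df = df.copy()
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    determined = df["cq"].dropna()
    if ((determined <= 0) | (determined > 40)).any():
        raise ValueError("determined Cq values must lie in (0, 40]")
    return df


def join_expression_clinical(expr: ExpressionMatrix,
                             clinical: pd.DataFrame) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Inner-join expression samples with clinical records, logging drops."""
    shared = [s for s in expr.sample_ids if s in set(clinical["sample_id"])]
    dropped_expr = sorted(set(expr.sample_ids) - set(shared))
    dropped_clin = sorted(set(clinical["sample_id"]) - set(shared))
    if dropped_expr:
        logger.warning("join: %d expression sample(s) without clinical data: %s",
                       len(dropped_expr), dropped_expr[:10])
    if dropped_clin:
        logger.warning("join: %d clinical record(s) without expression: %s",
                       len(dropped_clin), dropped_clin[:10])
    if len(shared) < 2:
        raise ValueError("fewer than 2 samples shared between expression and clinical")
    sub = ExpressionMatrix(expr.data[shared], expr.platform_tag)
    clin = clinical.set_index("sample_id").loc[shared].reset_index()
    return sub, clin
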