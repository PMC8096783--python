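"""From triplicate Cq wells to reduced-signature dECIF calls.

Replicates more than 0.5 cycles from their replicate median are discarded
as outliers, the rest averaged; a per-plate shift estimated from the
calibrator wells is subtracted; expression is the negated ΔCq against a
housekeeping gene (RPLP1 by default), so one cycle equals one log2 unit
of expression with amplification efficiency 2 assumed exact.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classifier import apply_reduced, assign_decif
from .datatypes import ExpressionMatrix, ReducedSignature, SignatureStatus
from .stats import AgreementResult, cohen_kappa, spearman_ci

logger = logging.getLogger("decif")

__all__ = [
    "OUTLIER_CYCLES",
    "aggregate_cq",
    "calibrator_correct",
    "normalize_dcq",
    "classify_from_qpcr",
    "cross_assay_agreement",
]

#: replicates further than this from the replicate median are discarded
OUTLIER_CYCLES = 0.5

CONTROL_SAMPLES = {"CALIBRATOR", "BLANK"}


def aggregate_cq(wells: pd.DataFrame) -> pd.DataFrame:
    """Collapse triplicates to one Cq per (plate, sample, gene).

    Undetermined (NaN) wells are excluded; among the determined replicates,
    any more than 0.5 cycles from the replicate median is dropped with an
    outlier flag. Fewer than 2 valid replicates flags the measurement as
    low-confidence; none leaves it missing. A blank with a determined Cq
    raises a plate-contamination warning.
    """
    blanks = wells[wells["sample_id"] == "BLANK"]
    bad_blanks = blanks["cq"].notna()
    if bad_blanks.any():
        plates = blanks.loc[bad_blanks, "plate_id"].unique().tolist()
        logger.warning("possible contamination: blank well(s) with a determined "
                       "Cq on plate(s) %s", plates)

    rows = []
    data = wells[wells["sample_id"] != "BLANK"]
    for (plate, sample, gene), grp in data.groupby(
            ["plate_id", "sample_id", "gene_id"], sort=False):
        cqs = grp["cq"].dropna().to_numpy()
        if cqs.size == 0:
            rows.append((plate, sample, gene, np.nan, "missing"))
            continue
        med = np.median(cqs)
        keep = cqs[np.abs(cqs - med) <= OUTLIER_CYCLES]
        flag = "ok"
        if keep.size < cqs.size:
            flag = "outlier_discarded"
        if keep.size < 2:
            flag = "low_confidence" if flag == "ok" else flag + "+low_confidence"
        rows.append((plate, sample, gene, float(keep.mean()), flag))
    return pd.DataFrame(rows, columns=["plate_id", "sample_id", "gene_id", "cq", "flag"])


def calibrator_correct(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Remove inter-plate shifts using the calibrator wells.

    The shift of a plate is the mean over genes of (calibrator Cq on that
    plate - cross-plate mean calibrator Cq of the gene); it is subtracted
    from every Cq on the plate. Without calibrator rows the table is
    returned unchanged (single-plate runs need no correction).
    """
    cal = cq_table[cq_table["sample_id"] == "CALIBRATOR"]
    if cal.empty:
        logger.info("no calibrator wells; skipping inter-plate correction")
        return cq_table.copy()
    per_gene = cal.groupby("gene_id")["cq"].transform("mean")
    dev = (cal["cq"] - per_gene).groupby(cal["plate_id"]).mean()
    out = cq_table.copy()
    out["cq"] = out["cq"] - out["plate_id"].map(dev).fillna(0.0)
    return out


def normalize_dcq(cq_table: pd.DataFrame, housekeeping_gene: str = "RPLP1"
                  ) -> pd.DataFrame:
    """ΔCq-normalized expression per (sample, gene).

    expression = -(Cq_gene - Cq_housekeeping), so higher expression means an
    earlier quantification cycle. Inter-plate calibrator correction is
    applied first. Samples lacking a housekeeping Cq are excluded and
    logged.
    """
    corrected = calibrator_correct(cq_table)
    corrected = corrected[~corrected["sample_id"].isin(CONTROL_SAMPLES)]
    hk = corrected[corrected["gene_id"] == housekeeping_gene].set_index("sample_id")["cq"]
    if hk.empty:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} absent from table")
    target = corrected[corrected["gene_id"] != housekeeping_gene].copy()
    target["hk_cq"] = target["sample_id"].map(hk)
    no_hk = target["hk_cq"].isna() & target["cq"].notna()
    if no_hk.any():
        excluded = target.loc[no_hk, "sample_id"].unique().tolist()
        logger.warning("excluding %d sample(s) without housekeeping Cq: %s",
                       len(excluded), excluded)
        target = target[~target["sample_id"].isin(excluded)]
    target["expression"] = -(target["cq"] - target["hk_cq"])
    return target[["sample_id", "gene_id", "expression"]]


def expression_matrix_from_dcq(dcq: pd.DataFrame, platform_tag: str = "qpcr"
                               ) -> ExpressionMatrix:
    """Pivot long-format ΔCq expression into a genes x samples matrix."""
    wide = dcq.pivot_table(index="gene_id", columns="sample_id",
                           values="expression", aggfunc="mean")
    return ExpressionMatrix(wide, platform_tag)


def classify_from_qpcr(dcq: pd.DataFrame, ecm3_sig: ReducedSignature,
                       ifn_sig: ReducedSignature) -> pd.DataFrame:
    """dECIF labels from ΔCq expression via the reduced signatures.

    ΔCq-derived expression is z-standardized within the cohort by
    :func:`decif.classifier.apply_reduced`, so per-gene assay offsets drop
    out; both reduced signatures are applied and combined into the joint
    and dichotomous variables.
    """
    expr = expression_matrix_from_dcq(dcq)
    ecm3 = apply_reduced(expr, ecm3_sig)
    ifn = apply_reduced(expr, ifn_sig)
    ecm3 = SignatureStatus("ECM3", ecm3.status, ecm3.score)
    ifn = SignatureStatus("IFN", ifn.status, ifn.score)
    return assign_decif(ecm3, ifn)


def cross_assay_agreement(labels_array: pd.DataFrame, labels_qpcr: pd.DataFrame,
                          expr_array: ExpressionMatrix | None = None,
                          dcq: pd.DataFrame | None = None
                          ) -> tuple[AgreementResult, pd.DataFrame]:
    """Agreement between array-based and qPCR-based dECIF calls.

    Cohen's kappa on the dichotomous labels of the matched samples, plus
    (when both expression sources are supplied) the per-gene Spearman
    correlation with its Fisher-z CI between platforms.
    """
    shared = labels_array.index.intersection(labels_qpcr.index)
    if len(shared) < 4:
        raise ValueError("need >= 4 matched samples across assays")
    a = labels_array.loc[shared, "dichotomous"] == "ECM3+/IFN-"
    b = labels_qpcr.loc[shared, "dichotomous"] == "ECM3+/IFN-"
    agreement = cohen_kappa(a.to_numpy(), b.to_numpy())

    per_gene = []
    if expr_array is not None and dcq is not None:
        qmat = expression_matrix_from_dcq(dcq)
        for g in qmat.gene_ids:
            if g not in expr_array.data.index:
                continue
            cols = [s for s in shared if s in qmat.data.columns]
            x = expr_array.data.loc[g, cols].to_numpy()
            y = qmat.data.loc[g, cols].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 4:
                r, lo, hi, _ = spearman_ci(x[ok], y[ok])
                per_gene.append((g, r, lo, hi, int(ok.sum())))
    table = pd.DataFrame(per_gene, columns=["gene_id", "r_s", "ci_low", "ci_high", "n"])
    return agreement, table
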