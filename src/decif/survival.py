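"""Kaplan–Meier estimation, log-rank comparison and Cox regression for the
prognostic evaluation of dECIF and other covariates.

Cox models use the Efron partial-likelihood correction for tied event
times and Wald-type confidence intervals, matching the HR / 95% CI /
p-value reporting style of clinical survival tables. Categorical terms are
entered as indicator contrasts against a declared reference category (the
putative better-prognosis one), so a hazard ratio above 1 flags the
at-risk category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger("decif")

__all__ = ["CoxResult", "km_estimate", "logrank_test", "cox_fit"]


@dataclass
class CoxResult:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    reference_category: str | None
    n: int
    adjusted_for: list

    def __post_init__(self):
        if self.hr <= 0:
            raise ValueError("hazard ratio must be positive")
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("CI must bracket the HR")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("os_time", "os_event"):
        if col not in records.columns:
            raise ValueError(f"records need an {col!r} column")
    if (records["os_time"] < 0).any():
        raise ValueError("negative follow-up time")
    if not records["os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be 0/1")
    return records


def km_estimate(records: pd.DataFrame, group: str | None = None
                ) -> tuple[dict, float]:
    """Product-limit survival estimate per group plus median follow-up.

    Returns ({group: step DataFrame with columns time, survival}, median
    follow-up in the time unit of the input, computed by reverse
    Kaplan–Meier on the censoring indicator).
    """
    records = _check_records(records)
    groups = {"all": records} if group is None else {
        str(g): sub for g, sub in records.groupby(group)}
    curves = {}
    for name, sub in groups.items():
        if sub.empty:
            raise ValueError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    rkm = KaplanMeierFitter()
    rkm.fit(records["os_time"], 1 - records["os_event"])
    median_followup = float(rkm.median_survival_time_)
    return curves, median_followup


def logrank_test(records: pd.DataFrame, group: str) -> tuple[float, float]:
    """Log-rank chi-square comparison of the group survival curves.

    df = number of groups - 1; requires >= 2 groups and at least one event.
    """
    records = _check_records(records)
    levels = records[group].unique()
    if len(levels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    if records["os_event"].sum() == 0:
        raise ValueError("log-rank undefined without events")
    for lev in levels:
        if (records[group] == lev).sum() == 0:  # pragma: no cover - defensive
            raise ValueError(f"group {lev!r} has no at-risk samples")
    res = multivariate_logrank_test(records["os_time"], records[group],
                                    records["os_event"])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(records: pd.DataFrame, terms: list[str],
            reference_map: dict[str, str] | None = None,
            confidence: float = 0.95) -> list[CoxResult]:
    """Cox proportional-hazards fit (Efron ties, Wald CI).

    ``terms`` may hold one (univariate) or two (bivariate adjusted)
    covariate names. Categorical covariates need a reference category in
    ``reference_map``; continuous covariates are entered untransformed.
    Monotone-likelihood fits (infinite HR) are flagged with an unbounded CI
    rather than silently reported.
    """
    records = _check_records(records).copy()
    if int(records["os_event"].sum()) == 0:
        raise ValueError("Cox fit needs at least one event")
    reference_map = reference_map or {}

    design = pd.DataFrame(index=records.index)
    colmeta = {}  # design column -> (term, reference or None)
    for term in terms:
        col = records[term]
        if col.dtype.kind in "ifu" and col.nunique() > 2:
            design[term] = col.astype(float)
            colmeta[term] = (term, None)
        else:
            levels = [str(v) for v in pd.unique(col.astype(str))]
            ref = reference_map.get(term)
            if ref is None:
                raise ValueError(f"categorical term {term!r} needs a reference category")
            if str(ref) not in levels:
                raise ValueError(f"reference {ref!r} not a level of {term!r}: {levels}")
            for lev in sorted(set(levels) - {str(ref)}):
                name = f"{term}[{lev}]"
                design[name] = (col.astype(str) == lev).astype(float)
                colmeta[name] = (term, str(ref))

    df = pd.concat([design,
                    records[["os_time", "os_event"]].astype(float)], axis=1)
    cph = CoxPHFitter(alpha=1 - confidence)
    cph.fit(df, duration_col="os_time", event_col="os_event")

    summary = cph.summary
    out = []
    n = len(df)
    lo_col = [c for c in summary.columns if c.startswith("exp(coef) lower")][0]
    hi_col = [c for c in summary.columns if c.startswith("exp(coef) upper")][0]
    for name in design.columns:
        row = summary.loc[name]
        hr = float(row["exp(coef)"])
        lo, hi = float(row[lo_col]), float(row[hi_col])
        if abs(float(row["coef"])) > 15:  # monotone likelihood / separation
            logger.warning("cox_fit: term %s shows monotone likelihood; CI unbounded", name)
            lo, hi = 0.0, np.inf
        term, ref = colmeta[name]
        out.append(CoxResult(term=name, hr=hr, ci_low=lo, ci_high=hi,
                             p_value=float(row["p"]), reference_category=ref,
                             n=n, adjusted_for=[t for t in terms if t != term]))
    return out


def cox_table(results: list[CoxResult]) -> pd.DataFrame:
    """Flatten Cox results into a report table (term, HR, CI, p)."""
    return pd.DataFrame(
        [{"term": r.term, "HR": r.hr, "ci_low": r.ci_low, "ci_high": r.ci_high,
          "p_value": r.p_value, "reference": r.reference_category, "n": r.n,
          "adjusted_for": ";".join(r.adjusted_for)} for r in results])
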