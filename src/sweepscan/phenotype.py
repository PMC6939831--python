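"""Phenotype-side analyses: otolith Sr:Ca life-history classification,
2^-ddCt relative expression with t-tests, and fold-change/p DEG calls.

Otolith Sr:Ca thresholds (ratios x1000): freshwater <= 3.0, brackish
(3.0, 7.0], seawater > 7.0.  A transect is called migratory when, after
3-point median smoothing, it contains a run of at least ``min_run``
consecutive non-freshwater points; otherwise resident.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FRESHWATER, MIGRATORY, SampleGrouping, ValidationError

log = logging.getLogger(__name__)

RESIDENT = "resident"
MIGRATORY_PATTERN = "migratory"


def classify_water(ratio: float) -> str:
    """Water type from one Sr:Ca ratio: freshwater / brackish / seawater."""
    if ratio < 0:
        raise ValidationError("Sr:Ca ratio must be non-negative")
    if ratio <= 3.0:
        return "freshwater"
    if ratio <= 7.0:
        return "brackish"
    return "seawater"


def _median3(x: np.ndarray) -> np.ndarray:
    """3-point running median; endpoints are left unsmoothed."""
    out = x.copy()
    if len(x) >= 3:
        stacked = np.stack([x[:-2], x[1:-1], x[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    return out


def classify_life_history(transect: pd.DataFrame, min_run: int = 3) -> str:
    """Resident vs migratory call from a core->edge Sr:Ca transect.

    ``transect`` needs columns ``distance_um`` (strictly increasing) and
    ``sr_ca_ratio``.  Single-point excursions are rejected by the median
    smoothing plus the run-length requirement.
    """
    if len(transect) < 10:
        raise ValidationError("transect needs at least 10 points")
    dist = transect["distance_um"].to_numpy(dtype=float)
    if not (np.diff(dist) > 0).all():
        raise ValidationError("transect distances must be strictly increasing")
    ratios = transect["sr_ca_ratio"].to_numpy(dtype=float)
    if (ratios < 0).any():
        raise ValidationError("Sr:Ca ratios must be non-negative")
    smoothed = _median3(ratios)
    non_fw = smoothed > 3.0
    run = best = 0
    for flag in non_fw:
        run = run + 1 if flag else 0
        best = max(best, run)
    return MIGRATORY_PATTERN if best >= min_run else RESIDENT


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt

def ddct_relative_expression(qpcr: pd.DataFrame, gene: str,
                             calibrator_group: str = FRESHWATER
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression by the 2^-ddCt method.

    Per sample, dCt = Ct(target) - Ct(reference); ddCt subtracts the
    calibrator group's mean dCt; RQ = 2^-ddCt.  The calibrator group's
    geometric-mean RQ is exactly 1 by construction.  Returns (per-sample
    table, per-group summary with geometric means).
    """
    sub = qpcr[qpcr["gene"] == gene].copy()
    sub = sub.dropna(subset=["ct_target", "ct_reference"])
    dropped = len(qpcr[qpcr["gene"] == gene]) - len(sub)
    if dropped:
        log.warning("ddct: dropped %d records with missing Ct", dropped)
    if not (sub["group"] == calibrator_group).any():
        raise ValidationError(f"calibrator group {calibrator_group!r} empty for {gene!r}")
    sub["dct"] = sub["ct_target"] - sub["ct_reference"]
    cal_mean = sub.loc[sub["group"] == calibrator_group, "dct"].mean()
    sub["ddct"] = sub["dct"] - cal_mean
    sub["rq"] = 2.0 ** (-sub["ddct"])
    summary = (sub.groupby("group")["rq"]
               .agg(geo_mean=lambda x: float(np.exp(np.mean(np.log(x)))),
                    n="count")
               .reset_index())
    return sub.reset_index(drop=True), summary


def two_sample_t(x, y, variant: str = "student") -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled-variance Student or Welch).

    Degenerate inputs: zero variance in both groups gives p = 1 when the
    means are equal and p = 0 (flagged in the log) when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        log.warning("two_sample_t: zero variance with unequal means (degenerate)")
        return float("inf"), 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def call_deg(expr: pd.DataFrame, grouping: SampleGrouping,
             fold_thr: float = 2.0, alpha: float = 0.05,
             variant: str = "student") -> pd.DataFrame:
    """Differential-expression flags per gene.

    ``expr`` is a genes x samples table (gene ids as index, sample ids as
    columns).  Fold change is larger group mean over smaller group mean,
    with the higher group recorded as direction; the p-value comes from a
    t-test on log2(x + 1).  A gene is flagged iff p < ``alpha`` and
    fold > ``fold_thr``.
    """
    mig = [s for s in expr.columns if grouping.assignment.get(s) == MIGRATORY]
    fw = [s for s in expr.columns if grouping.assignment.get(s) == FRESHWATER]
    if len(mig) < 2 or len(fw) < 2:
        raise ValidationError("both groups need at least 2 samples in expr")
    rows = []
    for gene, vals in expr.iterrows():
        xm = vals[mig].to_numpy(dtype=float)
        xf = vals[fw].to_numpy(dtype=float)
        mm, mf = xm.mean(), xf.mean()
        if mm == 0 and mf == 0:
            log.info("call_deg: gene %s is all zero", gene)
            rows.append({"gene": gene, "mean_mig": 0.0, "mean_fw": 0.0,
                         "fold": 1.0, "direction": "none", "p": 1.0,
                         "flagged": False})
            continue
        lo, hi = sorted([mm, mf])
        fold = float("inf") if lo == 0 else hi / lo
        direction = MIGRATORY if mm >= mf else FRESHWATER
        _, p = two_sample_t(np.log2(xm + 1), np.log2(xf + 1), variant=variant)
        rows.append({"gene": gene, "mean_mig": mm, "mean_fw": mf,
                     "fold": fold, "direction": direction, "p": p,
                     "flagged": bool(p < alpha and fold > fold_thr)})
    return pd.DataFrame(rows)
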