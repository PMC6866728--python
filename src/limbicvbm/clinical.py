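"""ROI grey matter versus clinical scores.

Clinical instruments (MDS-UPDRS subscales, GDS, ESS, HVLT, SCOPA-AUT, STAI)
are collected at repeated visits; the value used for each subject is the
one from the visit nearest the MRI scan date, with equidistant ties broken
to the earlier visit and a missing value at the chosen visit replaced by
the most recent non-missing value from *prior* visits. Association uses
Pearson correlation and, to guard against age/sex confounding, OLS of the
ROI mean on score + age + sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

PROVENANCE = ("nearest_visit", "filled_most_recent", "missing")


@dataclass
class ClinicalMatch:
    """One subject x score resolution with provenance."""

    subject_id: str
    score: str
    visit_date: pd.Timestamp | None
    value: float
    provenance: str


def match_nearest_visit(visits: pd.DataFrame, scan_dates: pd.Series,
                        scores: list[str] | None = None) -> pd.DataFrame:
    """Resolve each (subject, score) to the visit nearest the scan.

    ``visits`` is long format (subject_id, visit_date, score_name, value);
    ``scan_dates`` maps subject_id -> scan date. Rules: choose the visit
    minimising |visit - scan| (tie -> earlier visit); if the value there is
    missing, fill backward from the most recent earlier non-missing visit;
    otherwise provenance is "missing".
    """
    visits = visits.copy()
    visits["visit_date"] = pd.to_datetime(visits["visit_date"])
    if scores is None:
        scores = sorted(visits["score_name"].unique())
    out = []
    for sid, scan in scan_dates.items():
        scan = pd.to_datetime(scan)
        sub = visits[visits["subject_id"] == sid]
        for score in scores:
            rows = sub[sub["score_name"] == score].sort_values("visit_date")
            if rows.empty:
                out.append(ClinicalMatch(sid, score, None, np.nan,
                                         "missing"))
                continue
            deltas = (rows["visit_date"] - scan).abs()
            best = deltas.min()
            candidates = rows[deltas == best]
            chosen = candidates.sort_values("visit_date").iloc[0]
            value = chosen["value"]
            if pd.notna(value):
                out.append(ClinicalMatch(sid, score, chosen["visit_date"],
                                         float(value), "nearest_visit"))
                continue
            prior = rows[(rows["visit_date"] <= chosen["visit_date"]) &
                         rows["value"].notna()]
            if len(prior):
                fill = prior.sort_values("visit_date").iloc[-1]
                out.append(ClinicalMatch(sid, score, fill["visit_date"],
                                         float(fill["value"]),
                                         "filled_most_recent"))
            else:
                out.append(ClinicalMatch(sid, score, chosen["visit_date"],
                                         np.nan, "missing"))
    return pd.DataFrame([m.__dict__ for m in out])


def correlate_roi_score(roi_means: pd.Series, matched: pd.DataFrame,
                        score: str):
    """Pearson correlation between ROI means and one matched score.

    ``roi_means`` is indexed by subject_id; subjects whose match provenance
    is "missing" are dropped (count logged). Returns (r, p, n).
    """
    rows = matched[(matched["score"] == score)]
    n_missing = int((rows["provenance"] == "missing").sum())
    if n_missing:
        logger.info("correlate_roi_score(%s): dropping %d subject(s) with "
                    "no usable value", score, n_missing)
    rows = rows[rows["provenance"] != "missing"]
    common = rows[rows["subject_id"].isin(roi_means.index)]
    x = roi_means.loc[common["subject_id"]].to_numpy(dtype=float)
    y = common["value"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate variable: ROI means are constant")
    if np.ptp(y) == 0:
        raise ValueError(f"degenerate variable: score '{score}' is constant")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def adjusted_association(roi_means: np.ndarray, scores: np.ndarray,
                         ages: np.ndarray, sexes: np.ndarray):
    """OLS of ROI mean on score + age + sex; inference on the score term.

    Complete cases only (df = n - 4 > 0 required). Returns
    (t, p, coefficient) for the score coefficient. A collinear design —
    e.g. a single-sex sample — is a hard error.
    """
    roi = np.asarray(roi_means, dtype=float)
    score = np.asarray(scores, dtype=float)
    age = np.asarray(ages, dtype=float)
    sex = np.asarray(sexes)
    if sex.dtype.kind in "UOS":
        sex = (sex == "M").astype(float)
    sex = sex.astype(float)
    keep = ~(np.isnan(roi) | np.isnan(score) | np.isnan(age) | np.isnan(sex))
    roi, score, age, sex = roi[keep], score[keep], age[keep], sex[keep]
    if roi.size - 4 <= 0:
        raise ValueError("too few complete cases (need n > 4)")
    X = np.column_stack([np.ones(roi.size), score, age, sex])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("collinear design (score/age/sex); is sex or the "
                         "score constant in this sample?")
    fit = sm.OLS(roi, X).fit()
    return float(fit.tvalues[1]), float(fit.pvalues[1]), float(fit.params[1])
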