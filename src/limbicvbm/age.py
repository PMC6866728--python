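"""Cross-sectional age-related grey-matter change mapping.

Within each group, the per-voxel OLS slope of GM density on age (GM-units
per year, the reduced model with the group terms dropped) estimates the
predicted rate of age-related grey-matter decline. Two parallel fits are
kept deliberately:

* natural-unit slopes per group, so difference maps read in thousandths of
  GM density per year and can be thresholded at the published operating
  point (|difference| >= 0.002/year, clusters >= 20 voxels,
  26-connectivity);
* the per-group z-scored interaction fit (X = age, Y = local GM) whose t
  statistic on d tests whether decline is significantly steeper in
  patients, corrected by BH-FDR within an optional small-volume mask.

Sign convention: slopes are signed (negative = decline). Difference maps
report control_slope - pd_slope, so a positive value means *extra* decline
in patients; the sign is preserved in the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .clusters import connectivity_structure, label_clusters
from .glm import fdr_correct
from .interaction import GroupInteractionModel
from .volumes import BrainMask, CohortStack, StatMap, extract_roi_mean


def _ols_slopes(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-column OLS slope of Y on x: cov(x, y) / var(x)."""
    xc = x - x.mean()
    denom = (xc * xc).sum()
    return (xc @ (Y - Y.mean(axis=0))) / denom


def age_slope_map(stack: CohortStack, ages: np.ndarray) -> StatMap:
    """Natural-unit per-voxel age slope (GM density per year) for one group."""
    ages = np.asarray(ages, dtype=float)
    if stack.n_subjects < 3:
        raise ValueError("need >= 3 subjects for an age-slope map")
    if ages.shape != (stack.n_subjects,):
        raise ValueError("ages must align with stack rows")
    if np.ptp(ages) == 0:
        raise ValueError("zero age variance")
    slopes = _ols_slopes(stack.values, ages)
    return stack.to_stat_map(slopes, kind="slope",
                             contrast="GM-units per year")


def slope_difference_map(pd_slopes: StatMap, control_slopes: StatMap,
                         cutoff: float = 0.002, min_cluster: int = 20,
                         connectivity: int = 26,
                         atlas=None) -> tuple[StatMap, pd.DataFrame]:
    """Thresholded map of extra age-related decline in patients.

    difference = control_slope - pd_slope (positive where patients decline
    faster). Voxels with |difference| >= cutoff are kept, connected
    components smaller than ``min_cluster`` removed, signs preserved.
    """
    if pd_slopes.data.shape != control_slopes.data.shape or \
            not np.allclose(pd_slopes.affine, control_slopes.affine):
        raise ValueError("slope maps are not on the same grid")
    diff = control_slopes.data - pd_slopes.data
    keep = np.where(np.isfinite(diff), np.abs(diff) >= cutoff, False)
    labelled, n = ndi.label(keep, structure=connectivity_structure(connectivity))
    if n:
        sizes = np.bincount(labelled.ravel())
        small = sizes < min_cluster
        small[0] = False
        keep &= ~small[labelled]
    out = np.where(keep, diff, np.nan)
    dmap = StatMap(out, pd_slopes.affine, kind="slope_difference",
                   contrast="control - pd slope (GM-units/year)",
                   meta={"cutoff": cutoff, "min_cluster": min_cluster,
                         "connectivity": connectivity,
                         "sign": "positive = extra decline in pd"})
    absmap = StatMap(np.where(keep, np.abs(diff), np.nan), dmap.affine,
                     kind="|slope_difference|")
    table = label_clusters(absmap, cutoff - 1e-15, connectivity, atlas=atlas)
    return dmap, table


def age_interaction_test(stack: CohortStack, ages: np.ndarray,
                         groups: np.ndarray,
                         small_volume_mask: BrainMask | None = None,
                         q: float = 0.05):
    """Interaction test for steeper decline in patients, FDR-corrected.

    Fits Y = a + b*X + c*G + d*G*X with X = age and Y = local GM, both
    z-scored within group, then applies BH-FDR (q) to the two-sided p_d —
    inside ``small_volume_mask`` when given, else across the whole cohort
    mask. Returns (t_d StatMap, significant in-mask boolean vector, extras).
    """
    groups = np.asarray(groups)
    if groups.dtype.kind in "UOS":
        groups = (groups == "pd").astype(int)
    res = GroupInteractionModel(stack.values, np.asarray(ages, float),
                                groups).fit()
    tmap = stack.to_stat_map(res.t_d, kind="t_d", df=float(res.df),
                             contrast="group x age interaction")
    in_scope = np.ones(stack.n_voxels, dtype=bool)
    if small_volume_mask is not None:
        if small_volume_mask.data.shape != stack.mask.data.shape:
            raise ValueError("small-volume mask grid mismatch")
        in_scope = small_volume_mask.data[stack.mask.data]
        if not in_scope.any():
            raise ValueError("small-volume mask does not intersect the "
                             "cohort mask")
    reject = np.zeros(stack.n_voxels, dtype=bool)
    p_adj = np.full(stack.n_voxels, np.nan)
    reject[in_scope], p_adj[in_scope] = fdr_correct(res.p_d[in_scope], q=q)
    return tmap, reject, {"fit": res, "p_adj": p_adj, "in_scope": in_scope}


def roi_slope_comparison(stack: CohortStack, ages: np.ndarray,
                         groups: np.ndarray,
                         rois: dict[str, BrainMask]) -> pd.DataFrame:
    """Per-ROI age slopes by group plus the interaction test on ROI means.

    For each named ROI (lateralised masks are simply separate entries), the
    per-subject ROI mean is regressed on age within each group
    (natural-unit slope) and the z-scored interaction model supplies t_d
    and p_d for the slope difference.
    """
    ages = np.asarray(ages, dtype=float)
    groups = np.asarray(groups)
    if groups.dtype.kind in "UOS":
        groups = (groups == "pd").astype(int)
    rows = []
    for name, roi in rois.items():
        means = extract_roi_mean(stack, roi)
        s_ctrl = float(_ols_slopes(means[groups == 0, None],
                                   ages[groups == 0])[0])
        s_pd = float(_ols_slopes(means[groups == 1, None],
                                 ages[groups == 1])[0])
        fit = GroupInteractionModel(means, ages, groups).fit()
        rows.append({
            "roi": name,
            "slope_control": s_ctrl,
            "slope_pd": s_pd,
            "slope_difference": s_ctrl - s_pd,
            "t_d": float(np.atleast_1d(fit.t_d)[0]),
            "p_d": float(np.atleast_1d(fit.p_d)[0]),
            "df": fit.df,
        })
    return pd.DataFrame(rows)
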