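"""Seed-based structural covariance and its group-difference test.

A covariance map is the across-subject Pearson correlation, within one
group, between the mean GM density of a seed region (here, typically the
right amygdala cut from the group VBM result) and the GM density at every
other voxel. Group differences in covariance are tested voxel-wise with the
group-interaction regression (Y = seed GM, X = local GM, both z-scored
within group); the t statistic on the interaction coefficient d is the
test. Balanced random subsampling of the larger group (repeated, averaged)
removes the sample-size asymmetry between patients and controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import fdr_correct
from .clusters import label_clusters
from .interaction import GroupInteractionModel
from .volumes import CohortStack, StatMap


def pearson_map(y: np.ndarray, X: np.ndarray):
    """Vectorised Pearson r (and two-sided p) of a vector against columns.

    Zero-variance columns get r = 0 and are flagged.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sy = np.sqrt((yc * yc).sum())
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    zero = (sx == 0) | (sy == 0)
    denom = np.where(zero, 1.0, sx * sy)
    r = np.clip((yc @ Xc) / denom, -1.0, 1.0)
    r = np.where(zero, 0.0, r)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, np.nan, p)
    return r, p, zero


@dataclass
class CovarianceMap:
    """Within-group seed covariance: r map, p map and a display threshold."""

    r: StatMap
    p: StatMap
    n: int
    p_cutoff: float
    significant: np.ndarray = field(repr=False, default=None)
    zero_variance: np.ndarray = field(repr=False, default=None)


def seed_covariance_map(stack: CohortStack, seed_values: np.ndarray,
                        p_cutoff: float = 6e-8,
                        use_fdr: bool = False) -> CovarianceMap:
    """Pearson correlation of the seed mean with every in-mask voxel.

    ``p_cutoff`` is the fixed display threshold applied in the published
    maps (P < 6e-8); set ``use_fdr`` to threshold by Benjamini-Hochberg at
    ``p_cutoff`` as the principled alternative.
    """
    seed_values = np.asarray(seed_values, dtype=float)
    if stack.n_subjects < 3:
        raise ValueError("need >= 3 subjects for a covariance map")
    if seed_values.shape != (stack.n_subjects,):
        raise ValueError("seed values must align with stack rows")
    r, p, zero = pearson_map(seed_values, stack.values)
    if use_fdr:
        sig, _ = fdr_correct(p, q=p_cutoff)
    else:
        sig = np.where(np.isnan(p), False, p < p_cutoff)
    rmap = stack.to_stat_map(r, kind="r", contrast="seed covariance")
    pmap = stack.to_stat_map(p, kind="p")
    return CovarianceMap(rmap, pmap, stack.n_subjects, p_cutoff,
                         significant=sig, zero_variance=zero)


def balanced_subsample(indices, n_target: int, n_repeats: int = 100,
                       seed: int | None = None) -> list[np.ndarray]:
    """Uniform without-replacement subsets of a subject index list.

    Matches the larger group's size to the smaller one (e.g. draw 172 of
    366 patients); the degenerate case n_target == len(indices) returns the
    identity selection for every repeat.
    """
    indices = np.asarray(indices)
    if n_target > indices.size:
        raise ValueError(f"n_target={n_target} exceeds group size "
                         f"{indices.size}")
    rng = np.random.default_rng(seed)
    if n_target == indices.size:
        return [indices.copy() for _ in range(n_repeats)]
    return [rng.choice(indices, size=n_target, replace=False)
            for _ in range(n_repeats)]


def averaged_seed_covariance(stack: CohortStack, seed_values: np.ndarray,
                             n_target: int, n_repeats: int = 100,
                             seed: int | None = None,
                             p_cutoff: float = 6e-8) -> CovarianceMap:
    """Mean covariance map over repeated balanced subsamples of one group."""
    seed_values = np.asarray(seed_values, dtype=float)
    subsets = balanced_subsample(np.arange(stack.n_subjects), n_target,
                                 n_repeats, seed)
    acc = np.zeros(stack.n_voxels)
    for rows in subsets:
        r, _, _ = pearson_map(seed_values[rows], stack.values[rows])
        acc += r
    r_mean = acc / len(subsets)
    # p map for the averaged r is not defined; report the mean-r map with
    # the single-subsample n
    rmap = stack.to_stat_map(r_mean, kind="r",
                             contrast=f"mean over {n_repeats} subsamples")
    pmap = stack.to_stat_map(np.full(stack.n_voxels, np.nan), kind="p")
    return CovarianceMap(rmap, pmap, n_target, p_cutoff,
                         significant=None, zero_variance=None)


def interaction_difference_map(stack: CohortStack, seed_values: np.ndarray,
                               groups: np.ndarray,
                               correction: str = "fdr", q: float = 0.05,
                               cluster_forming_t: float = 4.0,
                               n_perm: int = 1000, connectivity: int = 26,
                               seed: int | None = None, atlas=None):
    """Voxel-wise interaction test for group differences in covariance.

    Fits Y = a + b*X + c*G + d*G*X per voxel with Y the (within-group
    z-scored) seed value and X the local GM, and maps t_d. Multiplicity is
    handled either by BH-FDR on the two-sided p_d ("fdr") or by
    permutation cluster-extent FWE on |t_d| ("cluster_fwe").

    Returns (t_d StatMap, cluster/voxel table, extras dict).
    """
    groups = np.asarray(groups)
    if groups.dtype.kind in "UOS":
        groups = (groups == "pd").astype(int)
    res = GroupInteractionModel(np.asarray(seed_values, dtype=float),
                                stack.values, groups).fit()
    tmap = stack.to_stat_map(res.t_d, kind="t_d", df=float(res.df),
                             contrast="group x local-GM interaction")
    extras = {"fit": res}
    if correction == "fdr":
        reject, p_adj = fdr_correct(res.p_d, q=q)
        extras["reject"] = reject
        extras["p_adj"] = p_adj
        absmap = StatMap(np.abs(tmap.data), tmap.affine, kind="|t_d|",
                         df=float(res.df))
        if reject.any():
            # clusterise the FDR-surviving voxels for reporting
            thr = float(np.abs(res.t_d[reject]).min()) - 1e-12
            table = label_clusters(absmap, thr, connectivity, atlas=atlas)
        else:
            from .clusters import CLUSTER_COLUMNS
            table = pd.DataFrame(columns=CLUSTER_COLUMNS)
        return tmap, table, extras
    if correction == "cluster_fwe":
        null, obs_table = _interaction_cluster_fwe(
            stack, seed_values, groups, res, cluster_forming_t, n_perm,
            connectivity, seed, atlas)
        extras["null_max_sizes"] = null
        return tmap, obs_table, extras
    raise ValueError("correction must be 'fdr' or 'cluster_fwe'")


def _interaction_cluster_fwe(stack, seed_values, groups, res,
                             cluster_forming_t, n_perm, connectivity,
                             seed, atlas):
    from .clusters import connectivity_structure, max_cluster_size
    rng = np.random.default_rng(seed)
    mask = stack.mask.data
    structure = connectivity_structure(connectivity)
    absmap = StatMap(np.abs(stack.unmask(res.t_d)), stack.mask.affine,
                     kind="|t_d|", df=float(res.df))
    table = label_clusters(absmap, cluster_forming_t, connectivity,
                           atlas=atlas)
    null = np.empty(n_perm, dtype=int)
    vol = np.zeros(mask.shape)
    seed_values = np.asarray(seed_values, dtype=float)
    for i in range(n_perm):
        gp = rng.permutation(groups)
        rp = GroupInteractionModel(seed_values, stack.values, gp).fit()
        vol.fill(-np.inf)
        vol[mask] = np.abs(rp.t_d)
        null[i] = max_cluster_size(vol > cluster_forming_t, structure)
    table = table.copy()
    table["p_corr"] = [(1 + (null >= s).sum()) / (n_perm + 1)
                       for s in table["size"]]
    return null, table
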