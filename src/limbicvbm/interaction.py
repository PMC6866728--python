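"""Group-by-covariate interaction regression.

The central model of the package:

    Y = a + b*X + c*G + d*G*X + e,    G in {0 = control, 1 = pd}

fitted by least squares, voxel-wise where needed. Before fitting, Y and X
are z-scored *within each group* ("per-group normalisation"), which makes
the model read in correlation units: the within-group slope b equals the
control group's Pearson r, b + d equals the patient group's r, and d is
exactly the correlation difference r_pd - r_control. The t statistic on d
(df = n - 4) tests for a group difference in covariance (covariance mode,
X = local GM, Y = seed GM) or in age slope (ageing mode, X = age,
Y = local GM).

X and Y may each be a single vector or a subjects x voxels matrix; the fit
is vectorised over voxels through the 4x4 normal equations assembled from
column-sum sufficient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def zscore_by_group(a: np.ndarray, groups: np.ndarray,
                    ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Z-score rows within each group along axis 0.

    Returns (z, degenerate) where ``degenerate`` flags columns whose
    within-group standard deviation is zero in some group (those columns are
    set to 0 there and should be excluded from inference).
    """
    a = np.asarray(a, dtype=float)
    vec = a.ndim == 1
    A = a[:, None] if vec else a.copy()
    A = A.astype(float, copy=True)
    degenerate = np.zeros(A.shape[1], dtype=bool)
    for g in np.unique(groups):
        rows = np.asarray(groups) == g
        sub = A[rows]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=ddof)
        bad = sd == 0
        degenerate |= bad
        sd = np.where(bad, 1.0, sd)
        A[rows] = (sub - mu) / sd
        A[np.ix_(rows, bad)] = 0.0
    return (A[:, 0], degenerate[:1].copy()) if vec else (A, degenerate)


class GroupInteractionModel:
    """Least-squares fit of Y on [1, X, G, G*X] with per-group z-scoring.

    Parameters
    ----------
    y, x : array, shape (n,) or (n, V)
        Response and covariate; either may vary per voxel. A scalar-column
        input is broadcast against the other argument's voxel dimension.
    groups : array of {0, 1} or {"control", "pd"}
        Group indicator per subject.
    normalise : bool
        Apply within-group z-scoring first (the default, matching the
        published procedure). Disable to fit on natural units.
    """

    def __init__(self, y, x, groups, normalise: bool = True):
        groups = np.asarray(groups)
        if groups.dtype.kind in "UOS":
            groups = (groups == "pd").astype(float)
        g = np.asarray(groups, dtype=float)
        if set(np.unique(g)) - {0.0, 1.0}:
            raise ValueError("groups must be coded 0 (control) / 1 (pd)")
        if min((g == 0).sum(), (g == 1).sum()) < 3:
            raise ValueError("need >= 3 subjects per group")
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        n = g.size
        if y.shape[0] != n or x.shape[0] != n:
            raise ValueError("y, x and groups must agree on subject count")
        if n - 4 <= 0:
            raise ValueError("df = n - 4 must be positive")
        self.g = g
        self.n = n
        self.normalise = normalise
        if normalise:
            y, ybad = zscore_by_group(y, g)
            x, xbad = zscore_by_group(x, g)
        else:
            ybad = np.zeros(1 if y.ndim == 1 else y.shape[1], dtype=bool)
            xbad = np.zeros(1 if x.ndim == 1 else x.shape[1], dtype=bool)
        self.y = y
        self.x = x
        self._ybad, self._xbad = ybad, xbad

    def fit(self) -> "GroupInteractionResults":
        g = self.g
        y = self.y if self.y.ndim == 2 else self.y[:, None]
        x = self.x if self.x.ndim == 2 else self.x[:, None]
        V = max(y.shape[1], x.shape[1])
        # broadcast the scalar-column argument across voxels lazily
        yb = np.broadcast_to(y, (self.n, V))
        xb = np.broadcast_to(x, (self.n, V))
        degenerate = np.zeros(V, dtype=bool)
        degenerate |= np.broadcast_to(self._ybad, (V,))
        degenerate |= np.broadcast_to(self._xbad, (V,))

        gx = g[:, None] * xb
        ones = np.ones(self.n)
        # sufficient statistics: column sums over subjects
        Sx = xb.sum(0)
        Sxx = (xb * xb).sum(0)
        Sg = np.full(V, g.sum())
        Sgx = gx.sum(0)
        Sgxx = (gx * xb).sum(0)
        nvec = np.full(V, float(self.n))
        A = np.empty((V, 4, 4))
        A[:, 0, 0] = nvec;  A[:, 0, 1] = Sx;   A[:, 0, 2] = Sg;  A[:, 0, 3] = Sgx
        A[:, 1, 0] = Sx;    A[:, 1, 1] = Sxx;  A[:, 1, 2] = Sgx; A[:, 1, 3] = Sgxx
        A[:, 2, 0] = Sg;    A[:, 2, 1] = Sgx;  A[:, 2, 2] = Sg;  A[:, 2, 3] = Sgx
        A[:, 3, 0] = Sgx;   A[:, 3, 1] = Sgxx; A[:, 3, 2] = Sgx; A[:, 3, 3] = Sgxx

        b = np.empty((V, 4))
        b[:, 0] = yb.sum(0)
        b[:, 1] = (xb * yb).sum(0)
        b[:, 2] = (g[:, None] * yb).sum(0)
        b[:, 3] = (gx * yb).sum(0)

        # guard singular systems (degenerate voxels) with identity designs
        sing = degenerate.copy()
        det_ok = np.abs(np.linalg.det(A)) > np.finfo(float).tiny
        sing |= ~det_ok
        A[sing] = np.eye(4)
        b[sing] = 0.0
        Ainv = np.linalg.inv(A)
        beta = np.einsum("vij,vj->vi", Ainv, b)

        Syy = (yb * yb).sum(0)
        rss = np.maximum(Syy - np.einsum("vi,vi->v", beta, b), 0.0)
        df = self.n - 4
        sigma2 = rss / df
        var_d = sigma2 * Ainv[:, 3, 3]
        with np.errstate(divide="ignore", invalid="ignore"):
            se_d = np.sqrt(var_d)
            t_d = beta[:, 3] / se_d
        t_d = np.where(sing, 0.0, t_d)
        p_d = np.where(sing, np.nan, 2.0 * stats.t.sf(np.abs(t_d), df))
        scalar = self.y.ndim == 1 and self.x.ndim == 1
        return GroupInteractionResults(beta, t_d, p_d, se_d, rss, df,
                                       sing, scalar, ones.size)


@dataclass
class GroupInteractionResults:
    """Coefficients (a, b, c, d) and the interaction test per voxel."""

    params: np.ndarray          # (V, 4): a, b, c, d
    t_d: np.ndarray
    p_d: np.ndarray
    se_d: np.ndarray
    rss: np.ndarray
    df: int
    degenerate: np.ndarray      # voxels excluded from inference
    _scalar: bool
    n: int

    @property
    def a(self):
        return self._maybe_scalar(self.params[:, 0])

    @property
    def b(self):
        return self._maybe_scalar(self.params[:, 1])

    @property
    def c(self):
        return self._maybe_scalar(self.params[:, 2])

    @property
    def d(self):
        return self._maybe_scalar(self.params[:, 3])

    def _maybe_scalar(self, arr):
        return float(arr[0]) if self._scalar else arr

    def summary(self) -> pd.DataFrame:
        """One-row-per-coefficient table for the scalar (ROI) case."""
        if not self._scalar:
            raise ValueError("summary() is for scalar fits; use the arrays "
                             "for voxel-wise results")
        names = ["intercept (a)", "slope (b)", "group offset (c)",
                 "group x covariate (d)"]
        t_d = float(self.t_d[0])
        rows = pd.DataFrame({
            "coef": self.params[0],
            "name": names,
        }).set_index("name")
        rows["t"] = [np.nan, np.nan, np.nan, t_d]
        rows["p"] = [np.nan, np.nan, np.nan, float(self.p_d[0])]
        rows["df"] = self.df
        return rows
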