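"""Residual spatial autocorrelation: Moran's I with a permutation null.

I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with W the total weight. The default weight scheme is row-standardized
k-nearest-neighbour (k = 8) weights on residence coordinates; an explicit
dense weight matrix may be supplied instead. Significance comes from
random permutations of the values across locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from migenv.geo import KM_PER_DEG_LAT


@dataclass
class MoranResult:
    I: float
    expected_I: float  # -1/(n-1)
    p_perm: float
    n_perm: int
    weight_scheme: str
    z_perm: float  # (I - mean of permuted I) / sd of permuted I


def _knn_neighbors(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """(n, k) neighbour index array (self excluded) on a locally scaled
    planar embedding of (lat, lon), adequate at study-region scale."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    k = min(k, n - 1)
    lat0 = np.radians(coords[:, 0].mean())
    xy = np.column_stack(
        [
            coords[:, 1] * KM_PER_DEG_LAT * np.cos(lat0),
            coords[:, 0] * KM_PER_DEG_LAT,
        ]
    )
    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=k + 1)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = idx[i][idx[i] != i]
        out[i] = row[:k]
    return out


def knn_weight_matrix(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardized k-nearest-neighbour weight matrix (self excluded)."""
    idx = _knn_neighbors(coords, k)
    n, kk = idx.shape
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), kk)
    W[rows, idx.ravel()] = 1.0 / kk
    return W


def _moran_stat(z: np.ndarray, W: np.ndarray) -> float:
    n = len(z)
    w_total = W.sum()
    num = z @ (W @ z)
    den = z @ z
    return float((n / w_total) * num / den)


def morans_i(
    values: np.ndarray,
    coords: np.ndarray | None = None,
    W: np.ndarray | None = None,
    k: int = 8,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> MoranResult:
    """Moran's I with a permutation p-value.

    Provide either ``coords`` (kNN weights are built) or a precomputed
    weight matrix ``W`` (rows are standardized to sum to one). Constant
    values leave the statistic undefined and raise.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs n >= 3")
    if np.allclose(x, x[0]):
        raise ValueError("Moran's I is undefined for constant values")
    idx = None
    if W is None:
        if coords is None:
            raise ValueError("provide coords or a weight matrix")
        idx = _knn_neighbors(coords, k=k)
        scheme = f"knn(k={min(k, n - 1)}), row-standardized"
    else:
        W = np.asarray(W, dtype=float)
        rs = W.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        W = W / rs
        scheme = "user, row-standardized"

    z = x - x.mean()
    if idx is not None:
        # sparse kNN path: row-standardized weights are 1/k per neighbour,
        # total weight n, so I = z.(Wz) / z.z
        def stat(zv):
            wz = zv[idx].mean(axis=1)
            return float(zv @ wz / (zv @ zv))

    else:

        def stat(zv):
            return _moran_stat(zv, W)

    i_obs = stat(z)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    i_perm = np.empty(n_perm)
    for b in range(n_perm):
        i_perm[b] = stat(z[rng.permutation(n)])
    if alternative == "greater":
        extreme = i_perm >= i_obs
    elif alternative == "less":
        extreme = i_perm <= i_obs
    elif alternative == "two-sided":
        extreme = np.abs(i_perm - expected) >= np.abs(i_obs - expected)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + int(extreme.sum())) / (n_perm + 1.0)
    sd = i_perm.std(ddof=1)
    zscore = (i_obs - i_perm.mean()) / sd if sd > 0 else np.nan
    return MoranResult(
        I=i_obs,
        expected_I=expected,
        p_perm=float(p),
        n_perm=n_perm,
        weight_scheme=scheme,
        z_perm=float(zscore),
    )
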