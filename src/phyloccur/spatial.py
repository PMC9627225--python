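"""Spatial filtering: Gabriel neighbor graph and Moran's eigenvector maps.

The occurrence model controls for inter-area distance with a single spatial
eigenvector.  The construction is the standard Moran's-eigenvector-map (MEM)
pipeline for a small set of sites: great-circle distances between area
centroids, a Gabriel neighbor graph on those distances, and the
eigendecomposition of the doubly centered binary adjacency
``Omega = H W H`` (``H = I - 11'/m``).  Eigenvectors are orthogonal spatial
patterns ordered by Moran's I (proportional to their eigenvalue); the
selected eigenvector — by default the one with the largest eigenvalue, i.e.
the broadest positive-autocorrelation gradient — enters the model as the
``theta`` covariate.

An alternative "distance" variant (eigenvectors of the doubly centered
squared-distance matrix, classical PCoA axes) is available via
``mem_variant="distance"`` in :func:`spatial_eigenvector`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AreaTable

__all__ = [
    "EARTH_RADIUS_KM",
    "MEMBasis",
    "haversine_matrix",
    "gabriel_graph",
    "mem_eigenvectors",
    "morans_i",
    "select_mem",
    "spatial_eigenvector",
]

#: IUGG mean Earth radius, fixed for bit-reproducibility.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class MEMBasis:
    """Moran eigenvector basis of a connectivity graph.

    ``vectors`` holds m-1 orthonormal, zero-sum columns sorted by eigenvalue
    descending; ``moran_i`` the Moran's I of each column under the same
    graph, which is the eigenvalue rescaled by m / S0.
    """

    vectors: pd.DataFrame  # areas x (m-1)
    eigenvalues: pd.Series
    moran_i: pd.Series


def haversine_matrix(areas: AreaTable) -> pd.DataFrame:
    """Great-circle distance matrix (km) between area centroids."""
    lat = np.radians(areas.data["lat"].to_numpy(dtype=float))
    lon = np.radians(areas.data["lon"].to_numpy(dtype=float))
    if np.any(np.abs(areas.data["lat"].to_numpy()) > 90):
        raise ValueError("latitude outside [-90, 90]")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=areas.areas, columns=areas.areas)


def gabriel_graph(distances: pd.DataFrame) -> pd.DataFrame:
    """Gabriel neighbor graph from a distance matrix.

    Edge (i, j) exists iff no third point k satisfies
    ``d(i,j)^2 > d(i,k)^2 + d(j,k)^2`` — the circle with ij as diameter is
    empty.  Applied directly to great-circle distances (no planar
    projection).
    """
    d = distances.to_numpy(dtype=float)
    m = d.shape[0]
    if m < 2:
        raise ValueError("need at least 2 points")
    off = d[~np.eye(m, dtype=bool)]
    if np.any(off <= 0):
        raise ValueError("duplicate centroids (zero off-diagonal distance)")
    d2 = d**2
    adj = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            others = np.delete(np.arange(m), [i, j])
            if not len(others) or np.all(d2[i, j] <= d2[i, others] + d2[j, others]):
                adj[i, j] = adj[j, i] = 1
    return pd.DataFrame(adj, index=distances.index, columns=distances.columns)


def _is_connected(adj: np.ndarray) -> bool:
    m = adj.shape[0]
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == m


def mem_eigenvectors(graph: pd.DataFrame) -> MEMBasis:
    """Moran eigenvector map of a binary connectivity graph.

    Eigendecomposes ``Omega = H W H`` restricted to the space orthogonal to
    the constant vector, returning the m-1 non-trivial eigenpairs sorted by
    eigenvalue descending.  Columns are exactly centered and orthonormal.
    """
    W = graph.to_numpy(dtype=float)
    m = W.shape[0]
    if not _is_connected(W):
        raise ValueError("connectivity graph is disconnected")
    H = np.eye(m) - np.ones((m, m)) / m
    omega = H @ W @ H
    # orthonormal basis of the centered subspace: Q from QR of H, dropping
    # the null direction, keeps eigenvectors exactly zero-sum
    q, _ = np.linalg.qr(H)
    # H has rank m-1; identify the m-1 columns spanning 1-perp
    keep = [j for j in range(m) if abs(q[:, j].sum()) < 1e-8][: m - 1]
    if len(keep) < m - 1:  # fallback: Helmert basis
        q = _helmert(m)
        keep = list(range(m - 1))
    B = q[:, keep]
    lam, E = np.linalg.eigh(B.T @ omega @ B)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    U = B @ E[:, order]
    # deterministic sign: largest-magnitude entry positive
    for j in range(U.shape[1]):
        k = int(np.argmax(np.abs(U[:, j])))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
    s0 = W.sum()
    names = [f"MEM{i + 1}" for i in range(m - 1)]
    return MEMBasis(
        vectors=pd.DataFrame(U, index=graph.index, columns=names),
        eigenvalues=pd.Series(lam, index=names),
        moran_i=pd.Series(lam * m / s0, index=names),
    )


def _helmert(m: int) -> np.ndarray:
    h = np.zeros((m, m - 1))
    for j in range(1, m):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.sqrt(j * (j + 1))
    return h


def morans_i(x: np.ndarray | pd.Series, graph: pd.DataFrame) -> float:
    """Moran's I of per-area values under binary weights.

    ``I = (m / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``.
    """
    xv = np.asarray(x, dtype=float)
    W = graph.to_numpy(dtype=float)
    m = len(xv)
    dev = xv - xv.mean()
    denom = float(dev @ dev)
    if denom == 0:
        raise ValueError("Moran's I undefined for constant x")
    return float(m / W.sum() * (dev @ W @ dev) / denom)


def select_mem(basis: MEMBasis) -> pd.Series:
    """Select the eigenvector with the largest eigenvalue (broadest
    positive-autocorrelation pattern); warns when no eigenvalue is positive.
    """
    if basis.vectors.shape[1] == 0:
        raise ValueError("empty MEM basis")
    if (basis.eigenvalues <= 0).all():
        warnings.warn(
            "no positively autocorrelated eigenvector; returning the "
            "largest-eigenvalue column anyway",
            stacklevel=2,
        )
    best = basis.eigenvalues.idxmax()
    return basis.vectors[best].rename("mem")


def spatial_eigenvector(areas: AreaTable,
                        mem_variant: str = "gabriel") -> pd.Series:
    """End-to-end theta: distances -> graph -> MEM -> selection.

    ``mem_variant="gabriel"`` (default) decomposes the binary Gabriel
    adjacency; ``"distance"`` decomposes ``-0.5 * H D^2 H`` (classical PCoA
    of the distance matrix itself).
    """
    d = haversine_matrix(areas)
    if mem_variant == "gabriel":
        basis = mem_eigenvectors(gabriel_graph(d))
    elif mem_variant == "distance":
        m = d.shape[0]
        H = np.eye(m) - np.ones((m, m)) / m
        omega = -0.5 * H @ (d.to_numpy() ** 2) @ H
        lam, U = np.linalg.eigh(omega)
        order = np.argsort(lam)[::-1][: m - 1]
        U = U[:, order]
        for j in range(U.shape[1]):
            k = int(np.argmax(np.abs(U[:, j])))
            if U[k, j] < 0:
                U[:, j] = -U[:, j]
        names = [f"MEM{i + 1}" for i in range(m - 1)]
        basis = MEMBasis(
            vectors=pd.DataFrame(U, index=d.index, columns=names),
            eigenvalues=pd.Series(lam[order], index=names),
            moran_i=pd.Series(np.nan, index=names),
        )
    else:
        raise ValueError(f"unknown mem_variant: {mem_variant!r}")
    return select_mem(basis)
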