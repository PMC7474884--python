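"""Spatial eigenvector bases (MEM and AEM) from site coordinates.

Moran's eigenvector maps (MEMs) are the eigenvectors of a doubly centred
spatial weighting matrix ``W = B * A`` (Hadamard product), where ``B`` is a
binary connectivity matrix (here: minimum spanning tree or Delaunay
triangulation) and ``A`` a distance-derived weight matrix. Eigenvectors with
positive eigenvalues describe positively autocorrelated spatial patterns;
larger eigenvalues correspond to broader spatial scales. Asymmetric
eigenvector maps (AEMs) are the directional analogue for processes
constrained by a directed network such as a river: they are the left singular
vectors of the column-centred sites-by-edges path incidence matrix.

Coordinates are planar throughout; geographic coordinates must be projected
before use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, distance_matrix

__all__ = [
    "EdgeList",
    "SpatialWeighting",
    "EigenBasis",
    "read_coordinates",
    "pairwise_distances",
    "mst_edges",
    "delaunay_edges",
    "weight_matrix",
    "mem_basis",
    "morans_i",
    "aem_basis",
]

#: virtual upstream origin used in directed (AEM) edge lists
ORIGIN = -1

WEIGHT_TRANSFORMS = ("linear", "inverse", "raw")


@dataclass(frozen=True)
class EdgeList:
    """Edges of a connectivity graph.

    ``edges`` is a (k, 2) integer array of site indices. For undirected
    graphs (MEM) each pair is stored with ``i < j``; for directed graphs
    (AEM) pairs are (upstream, downstream) and the virtual origin is coded
    as :data:`ORIGIN`.
    """

    edges: np.ndarray
    lengths: np.ndarray | None = None
    directed: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        object.__setattr__(self, "edges", e)
        if np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-edges are not allowed")
        if self.lengths is not None:
            ln = np.asarray(self.lengths, dtype=float)
            if ln.shape != (len(e),):
                raise ValueError("lengths must have one entry per edge")
            object.__setattr__(self, "lengths", ln)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class SpatialWeighting:
    """Spatial weighting matrix W = B * A (entrywise).

    B is the binary connectivity matrix, A the distance-derived weight
    matrix; both n x n with zero diagonals. W is symmetric and non-negative.
    """

    B: np.ndarray
    A: np.ndarray
    W: np.ndarray

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class EigenBasis:
    """Retained spatial eigenvectors.

    ``vectors`` is n x m with orthonormal, mean-zero columns ordered by
    descending ``eigenvalues`` (MEM eigenvalues, or AEM singular values).
    The sign of each column is fixed so its first non-zero loading is
    positive, making the basis reproducible bit-for-bit.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    kind: str = "MEM"
    morans: np.ndarray | None = field(default=None, compare=False)

    @property
    def m(self) -> int:
        return self.vectors.shape[1]

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


def read_coordinates(path) -> pd.DataFrame:
    """Read a site coordinate table (columns ``site,x,y``, header required)."""
    df = pd.read_csv(path)
    missing = {"site", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinate file lacks columns: {sorted(missing)}")
    return df


def _as_xy(coords) -> np.ndarray:
    """Coerce a coordinate table or array to an (n, 2) float array."""
    if isinstance(coords, pd.DataFrame):
        xy = coords[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(coords, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("coordinates must be an (n, 2) table of x, y")
    if np.isnan(xy).any():
        raise ValueError("coordinates contain missing values")
    return xy


def pairwise_distances(coords) -> np.ndarray:
    """Euclidean distance matrix between sites.

    Raises if any two sites share a position, naming the offending pair.
    """
    xy = _as_xy(coords)
    if len(xy) < 2:
        raise ValueError("need at least two sites")
    d = distance_matrix(xy, xy)
    dup = np.argwhere((d == 0) & ~np.eye(len(xy), dtype=bool))
    if len(dup):
        i, j = dup[0]
        raise ValueError(f"duplicate site positions: sites {i} and {j}")
    return d


def mst_edges(d: np.ndarray) -> EdgeList:
    """Minimum spanning tree over the full distance matrix.

    Kruskal's algorithm on edges pre-sorted lexicographically, so equal
    lengths are broken deterministically by the lower edge index.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("minimum spanning tree needs at least two sites")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=d[i, j])
    # kruskal uses a stable sort on weight, so insertion (lexicographic)
    # order breaks ties
    tree = list(nx.minimum_spanning_edges(g, algorithm="kruskal", data=False))
    edges = np.array(sorted(tuple(sorted(e)) for e in tree), dtype=int)
    return EdgeList(edges=edges, lengths=d[edges[:, 0], edges[:, 1]])


def delaunay_edges(coords) -> EdgeList:
    """Edge set of the Delaunay triangulation of the sites."""
    xy = _as_xy(coords)
    if len(xy) < 3:
        raise ValueError("Delaunay triangulation needs at least three sites")
    try:
        tri = Delaunay(xy)
    except QhullError as err:  # all collinear, or otherwise degenerate
        raise ValueError(f"degenerate (collinear?) coordinates: {err}") from err
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                pairs.add((min(i, j), max(i, j)))
    edges = np.array(sorted(pairs), dtype=int)
    d = distance_matrix(xy, xy)
    return EdgeList(edges=edges, lengths=d[edges[:, 0], edges[:, 1]])


def weight_matrix(edges: EdgeList, d: np.ndarray, transform: str = "linear") -> SpatialWeighting:
    """Spatial weighting matrix W = B * A from a connectivity edge list.

    transform
        ``linear`` (default): similarity f(d) = 1 - d / d_max with d_max the
        largest distance among connected pairs, so closer neighbours get
        larger weights; ``inverse``: f(d) = 1 / d; ``raw``: f(d) = d.
    """
    if transform not in WEIGHT_TRANSFORMS:
        raise ValueError(
            f"unknown weight transform {transform!r}; choose from {WEIGHT_TRANSFORMS}"
        )
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    B = np.zeros((n, n))
    e = edges.edges
    B[e[:, 0], e[:, 1]] = 1.0
    B[e[:, 1], e[:, 0]] = 1.0
    np.fill_diagonal(B, 0.0)
    if transform == "linear":
        dmax = d[B > 0].max()
        A = 1.0 - d / dmax
    elif transform == "inverse":
        with np.errstate(divide="ignore"):
            A = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    else:  # raw
        A = d.copy()
    np.fill_diagonal(A, 0.0)
    W = B * A
    W = (W + W.T) / 2.0
    return SpatialWeighting(B=B, A=A, W=W)


def _fix_signs(vectors: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip eigenvector signs so the first non-zero loading is positive."""
    v = vectors.copy()
    for k in range(v.shape[1]):
        col = v[:, k]
        nz = np.flatnonzero(np.abs(col) > tol)
        if len(nz) and col[nz[0]] < 0:
            v[:, k] = -col
    return v


def mem_basis(w: SpatialWeighting, tol: float = 1e-9) -> EigenBasis:
    """Moran's eigenvector maps: eigenvectors of the doubly centred W.

    Computes the eigendecomposition of ``H W H`` with the centring projector
    ``H = I - 11'/n`` and retains eigenvectors whose eigenvalue exceeds
    ``tol * max |eigenvalue|`` (the positive-autocorrelation half of the
    spectrum), ordered by descending eigenvalue.
    """
    W = np.asarray(w.W if isinstance(w, SpatialWeighting) else w, dtype=float)
    n = W.shape[0]
    if n < 3:
        raise ValueError("MEM basis needs at least three sites")
    W = (W + W.T) / 2.0
    H = np.eye(n) - np.ones((n, n)) / n
    M = H @ W @ H
    M = (M + M.T) / 2.0
    eigval, eigvec = np.linalg.eigh(M)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > tol * np.abs(eigval).max()
    if not keep.any():
        warnings.warn("no positive eigenvalues: empty MEM basis", stacklevel=2)
    vectors = _fix_signs(eigvec[:, keep])
    return EigenBasis(vectors=vectors, eigenvalues=eigval[keep], kind="MEM")


def morans_i(v: np.ndarray, w) -> float:
    """Moran's I spatial autocorrelation of ``v`` under weighting ``w``.

    I = (n / S0) * (v~' W v~) / (v~' v~) with v~ the centred vector and
    S0 the sum of all weights. Under an exchangeable null its expectation
    is -1/(n-1).
    """
    W = np.asarray(w.W if isinstance(w, SpatialWeighting) else w, dtype=float)
    v = np.asarray(v, dtype=float).ravel()
    n = len(v)
    if W.shape != (n, n):
        raise ValueError("weight matrix does not match vector length")
    vt = v - v.mean()
    ss = vt @ vt
    if ss == 0:
        raise ValueError("zero variance: Moran's I undefined for a constant vector")
    s0 = W.sum()
    if s0 <= 0:
        raise ValueError("sum of weights must be positive")
    return float((n / s0) * (vt @ W @ vt) / ss)


def _paths_from_origin(edges: np.ndarray, n_sites: int) -> np.ndarray:
    """Sites-by-edges incidence: E[i, k] = 1 iff edge k lies on origin->i."""
    children: dict[int, list[tuple[int, int]]] = {}
    indeg = np.zeros(n_sites, dtype=int)
    for k, (a, b) in enumerate(edges):
        if b == ORIGIN or not (0 <= b < n_sites):
            raise ValueError(f"edge {k}: invalid downstream node {b}")
        if a != ORIGIN and not (0 <= a < n_sites):
            raise ValueError(f"edge {k}: invalid upstream node {a}")
        children.setdefault(int(a), []).append((int(b), k))
        indeg[b] += 1
    if np.any(indeg > 1):
        raise ValueError("network is not a tree: a site has two incoming edges")
    E = np.zeros((n_sites, len(edges)))
    seen = np.zeros(n_sites, dtype=bool)
    stack = [(ORIGIN, np.zeros(len(edges)))]
    while stack:
        node, path = stack.pop()
        for child, k in children.get(node, ()):
            if seen[child]:
                raise ValueError("network contains a cycle")
            seen[child] = True
            row = path.copy()
            row[k] = 1.0
            E[child] = row
            stack.append((child, row))
    if not seen.all():
        missing = np.flatnonzero(~seen)
        raise ValueError(f"sites not reachable from origin: {missing.tolist()}")
    return E


def aem_basis(
    network: EdgeList,
    w_sym,
    edge_weights: np.ndarray | None = None,
    tol: float = 1e-9,
) -> EigenBasis:
    """Asymmetric eigenvector maps for a directed (river-like) network.

    Builds the sites-by-edges incidence matrix E (E[i, k] = 1 when edge k
    lies on the directed path from the origin to site i, optionally scaled
    by ``edge_weights``), centres its columns and takes the singular value
    decomposition. Left singular vectors are retained when their singular
    value is positive and their Moran's I on the symmetrised connectivity
    ``w_sym`` exceeds the null expectation -1/(n-1), i.e. only positively
    autocorrelated directional patterns are kept.
    """
    if not network.directed:
        raise ValueError("AEM needs a directed edge list")
    W = np.asarray(w_sym.W if isinstance(w_sym, SpatialWeighting) else w_sym, dtype=float)
    n = W.shape[0]
    E = _paths_from_origin(network.edges, n)
    if edge_weights is not None:
        ew = np.asarray(edge_weights, dtype=float)
        if ew.shape != (E.shape[1],):
            raise ValueError("edge_weights must have one entry per edge")
        E = E * ew
    Ec = E - E.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Ec, full_matrices=False)
    keep_sv = s > tol * s.max()
    U, s = U[:, keep_sv], s[keep_sv]
    null = -1.0 / (n - 1)
    moran = np.array([morans_i(U[:, k], W) for k in range(U.shape[1])])
    keep = moran > null
    vectors = _fix_signs(U[:, keep])
    return EigenBasis(
        vectors=vectors, eigenvalues=s[keep], kind="AEM", morans=moran[keep]
    )
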