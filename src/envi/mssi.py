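"""MSSI: multiscale spectral similarity index for segmented spatial data.

A graph-based analog of multiscale SSIM (MS-SSIM) from image quality
assessment. Two per-cell signals over the same tissue are compared on a
five-level pyramid obtained by repeatedly coarsening the spatial
k-nearest-neighbor graph of segmented cells by a factor of two (heavy-edge
matching with mean pooling). At each scale the SSIM luminance / contrast /
structure components are evaluated on the pooled signals, and MSSI is their
weighted geometric mean:

    MSSI(X, Y, D) = l_5^a5 * prod_s c_s^as * s_s^as,   s = 1..5,

with the canonical MS-SSIM exponents a = (0.0448, 0.2856, 0.3001, 0.2363,
0.1333). Luminance enters only at the coarsest scale. Signals are min-max
normalized once at the original scale and never re-normalized after
pooling. A negative structure term (anti-correlation) is clipped to zero,
so anti-correlation at any scale drives the score to its floor of 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

MS_SSIM_ALPHA = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass
class MssiConfig:
    alpha: tuple = MS_SSIM_ALPHA
    k_graph: int = 8
    n_scales: int = 5
    c1_coef: float = 0.01
    c2_coef: float = 0.03

    def __post_init__(self) -> None:
        if len(self.alpha) != self.n_scales:
            raise ValueError("need one weight per scale")


@dataclass
class SpatialGraph:
    """Symmetric weighted adjacency over segmented cells (no self-loops)."""

    adjacency: sp.csr_matrix
    node_sizes: np.ndarray  # cells pooled into each node

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class SsimComponents:
    l: float
    c: float
    s: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    sigma_xy: float
    M: float


@dataclass
class CoarseningPyramid:
    graphs: list
    operators: list  # row-stochastic (mean-pooling) matrices between levels
    signals_x: list
    signals_y: list


def build_spatial_graph(coords: np.ndarray, k_graph: int = 8) -> SpatialGraph:
    """Symmetrized unweighted kNN graph of cell coordinates."""
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two cells")
    if k_graph >= n:
        raise ValueError(f"k_graph={k_graph} must be < number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k_graph + 1).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)[:, 1:]
    rows = np.repeat(np.arange(n), k_graph)
    A = sp.csr_matrix(
        (np.ones(n * k_graph), (rows, idx.ravel())), shape=(n, n)
    )
    A = A.maximum(A.T)
    A.setdiag(0)
    A.eliminate_zeros()
    return SpatialGraph(adjacency=A.tocsr(), node_sizes=np.ones(n))


def coarsen_once(g: SpatialGraph, x: np.ndarray, y: np.ndarray):
    """Halve the graph by heavy-edge matching; mean-pool the signals.

    Nodes are greedily paired with their heaviest-edged unmatched neighbor
    (connectivity-driven pooling); unmatched or isolated nodes pass through.
    Returns the coarse graph, the row-stochastic pooling operator ``C`` with
    ``x' = C x``, and the pooled signals.
    """
    n = g.n_nodes
    if n < 2:
        return g, sp.identity(n, format="csr"), np.asarray(x), np.asarray(y)
    A = g.adjacency.tocsr()
    matched = np.full(n, -1, dtype=np.intp)
    # visit nodes in ascending degree so peripheral nodes pair first
    order = np.argsort(np.diff(A.indptr), kind="stable")
    for i in order:
        if matched[i] >= 0:
            continue
        start, end = A.indptr[i], A.indptr[i + 1]
        nbrs = A.indices[start:end]
        wts = A.data[start:end]
        best, best_w = -1, -np.inf
        for j, w in zip(nbrs, wts):
            if matched[j] < 0 and j != i and (w > best_w or (w == best_w and j < best)):
                best, best_w = j, w
        if best >= 0:
            matched[i] = best
            matched[best] = i
    # assign cluster ids
    cluster = np.full(n, -1, dtype=np.intp)
    nxt = 0
    for i in range(n):
        if cluster[i] >= 0:
            continue
        cluster[i] = nxt
        if matched[i] >= 0:
            cluster[matched[i]] = nxt
        nxt += 1
    m = nxt
    sizes_fine = g.node_sizes
    # mean pooling weighted by underlying cell counts, so multi-level means
    # stay means over original cells
    P = sp.csr_matrix((sizes_fine, (cluster, np.arange(n))), shape=(m, n))
    cluster_mass = np.asarray(P.sum(axis=1)).ravel()
    C = sp.diags(1.0 / cluster_mass) @ P
    x2 = C @ np.asarray(x, dtype=np.float64)
    y2 = C @ np.asarray(y, dtype=np.float64)
    A2 = (P @ A @ P.T).tocsr()
    A2.setdiag(0)
    A2.eliminate_zeros()
    g2 = SpatialGraph(adjacency=A2, node_sizes=cluster_mass)
    return g2, C.tocsr(), x2, y2


def build_pyramid(
    coords: np.ndarray, x: np.ndarray, y: np.ndarray, config: MssiConfig
) -> CoarseningPyramid:
    g = build_spatial_graph(coords, config.k_graph)
    graphs, ops = [g], []
    xs, ys = [np.asarray(x, dtype=np.float64)], [np.asarray(y, dtype=np.float64)]
    for _ in range(config.n_scales - 1):
        g, C, xi, yi = coarsen_once(graphs[-1], xs[-1], ys[-1])
        graphs.append(g)
        ops.append(C)
        xs.append(xi)
        ys.append(yi)
    return CoarseningPyramid(graphs=graphs, operators=ops, signals_x=xs, signals_y=ys)


def ssim_components(
    x: np.ndarray,
    y: np.ndarray,
    M: float,
    c1_coef: float = 0.01,
    c2_coef: float = 0.03,
) -> SsimComponents:
    """Luminance, contrast and structure terms of SSIM between two vectors.

    Standard constants C1 = (c1 M)^2, C2 = (c2 M)^2, C3 = C2 / 2 with M the
    dynamic range; the structure term is clipped below at 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("signals must share a length")
    if x.size < 2:
        raise ValueError("need at least two values per signal")
    if not M > 0:
        raise ValueError("dynamic range M must be positive")
    C1 = (c1_coef * M) ** 2
    C2 = (c2_coef * M) ** 2
    C3 = C2 / 2.0
    mu_x, mu_y = x.mean(), y.mean()
    sigma_x = x.std()
    sigma_y = y.std()
    sigma_xy = ((x - mu_x) * (y - mu_y)).mean()
    l = (2 * mu_x * mu_y + C1) / (mu_x**2 + mu_y**2 + C1)
    c = (2 * sigma_x * sigma_y + C2) / (sigma_x**2 + sigma_y**2 + C2)
    s = (sigma_xy + C3) / (sigma_x * sigma_y + C3)
    s = max(s, 0.0)
    return SsimComponents(
        l=float(l), c=float(c), s=float(min(s, 1.0)),
        mu_x=float(mu_x), mu_y=float(mu_y),
        sigma_x=float(sigma_x), sigma_y=float(sigma_y),
        sigma_xy=float(sigma_xy), M=float(M),
    )


def _minmax(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi <= lo:  # constant signal: normalization degenerate, leave as-is
        return v.copy()
    return (v - lo) / (hi - lo)


def mssi(
    x: np.ndarray,
    y: np.ndarray,
    coords: np.ndarray,
    config: MssiConfig | None = None,
) -> float:
    """Multiscale spectral similarity between two per-cell signals.

    Scores lie in [0, 1]; 1 for identical (or positively affine-related)
    signals, 0 whenever the signals are anti-correlated at any pyramid
    scale. Invariant to positive affine transforms of either input because
    of the original-scale min-max normalization.
    """
    if config is None:
        config = MssiConfig()
    x = _minmax(x)
    y = _minmax(y)
    if x.shape != y.shape:
        raise ValueError("signals must share a length")
    pyr = build_pyramid(coords, x, y, config)
    score = 1.0
    for s_idx in range(config.n_scales):
        xs, ys = pyr.signals_x[s_idx], pyr.signals_y[s_idx]
        M = float(max(xs.max(), ys.max()))
        if M <= 0:
            M = 1.0
        comp = ssim_components(xs, ys, M, config.c1_coef, config.c2_coef)
        a = config.alpha[s_idx]
        score *= (comp.c ** a) * (comp.s ** a)
        if s_idx == config.n_scales - 1:
            score *= comp.l ** a
    return float(min(max(score, 0.0), 1.0))


def mssi_table(
    truth: np.ndarray,
    pred: np.ndarray,
    coords: np.ndarray,
    gene_names,
    config: MssiConfig | None = None,
) -> dict:
    """Per-gene MSSI between matched columns of two cells x genes matrices."""
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.shape != pred.shape:
        raise ValueError("matrices must share a shape")
    return {
        str(g): mssi(truth[:, j], pred[:, j], coords, config)
        for j, g in enumerate(gene_names)
    }
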