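"""COVET: the covariance-environment representation of cellular niches.

A cell's niche is the expression of its ``k`` spatially nearest neighbors.
COVET summarizes the niche as a *shifted* gene-gene covariance matrix,

    Sigma_i = (1/k) (E_i - Xbar)^T (E_i - Xbar),

where ``E_i`` is the ``k x g`` niche expression matrix and ``Xbar`` is the
dataset-wide mean expression. Shifting every niche against the same
reference mean keeps the matrices directly comparable while preserving
positive semi-definiteness (each is a Gramian).

Niches are compared with optimal-transport geometry on covariances. The
exact metric is the Frechet (Bures) distance between zero-mean Gaussians,

    Frechet(A, B) = Tr A + Tr B - 2 Tr (A^1/2 B A^1/2)^1/2,

and the approximate-optimal-transport (AOT) variant swaps the square root
and the product, which collapses to plain Euclidean distance between matrix
square roots (MSQRs). We report the unsquared Frobenius norm ||A^1/2 -
B^1/2||_F, a true metric whose square is the swapped-trace expression; any
Euclidean-distance algorithm (kNN, clustering, diffusion maps, UMAP) can
then run directly on flattened MSQRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

from .data import SpatialDataset

DEFAULT_K = 8  # immediate niche of a cell in most tissues


# ---------------------------------------------------------------------------
# niche construction


@dataclass
class NicheTensor:
    """Per-cell niches: neighbor indices and their expression profiles."""

    neighbor_indices: np.ndarray  # (n, k) int
    niche_expression: np.ndarray  # (n, k, g') float
    niche_genes: np.ndarray
    k: int
    include_self: bool
    transform: str = "raw"


@dataclass
class CovetSet:
    """Shifted-covariance matrices and their square roots for every cell."""

    matrices: np.ndarray  # (n, g', g')
    sqrt_matrices: np.ndarray  # (n, g', g')
    global_mean: np.ndarray  # (g',)
    niche_genes: np.ndarray
    k: int

    @property
    def n_cells(self) -> int:
        return self.matrices.shape[0]

    def flattened_sqrts(self) -> np.ndarray:
        """(n, g'*g') view of MSQRs; Euclidean distance here is the AOT metric."""
        n = self.sqrt_matrices.shape[0]
        return self.sqrt_matrices.reshape(n, -1)


@dataclass
class DistanceMatrix:
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("distance matrix must be square")


def spatial_knn_indices(
    coords: np.ndarray, k: int, include_self: bool = False
) -> np.ndarray:
    """Indices of each cell's ``k`` nearest cells by Euclidean coordinate distance.

    Distance ties are broken by ascending cell index so that gridded
    coordinates give deterministic niches.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    limit = n if include_self else n - 1
    if k > limit:
        raise ValueError(f"k={k} too large for {n} cells (include_self={include_self})")
    nn = NearestNeighbors(n_neighbors=min(n, k + 1)).fit(coords)
    dist, idx = nn.kneighbors(coords)
    # stable re-sort on (distance, index) for deterministic tie-breaks
    order = np.lexsort((idx, dist), axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    dist = np.take_along_axis(dist, order, axis=1)
    out = np.empty((n, k), dtype=np.intp)
    for i in range(n):
        row = idx[i]
        if not include_self:
            row = row[row != i]
        out[i] = row[:k]
    return out


def build_niche_tensor(
    ds: SpatialDataset,
    k: int = DEFAULT_K,
    niche_genes=None,
    include_self: bool = False,
    transform: str = "raw",
) -> NicheTensor:
    """Collect each cell's k-nearest-neighbor expression into an (n, k, g') tensor.

    Parameters
    ----------
    ds
        Spatial dataset providing counts and coordinates.
    k
        Niche size; the k spatially nearest cells (excluding the focal cell
        unless ``include_self``).
    niche_genes
        Subset of the panel used for the niche representation; ``None`` uses
        the full panel.
    transform
        ``"raw"`` (default, counts as measured) or ``"log1p"``.
    """
    if transform not in ("raw", "log1p"):
        raise ValueError(f"unknown transform {transform!r}")
    if niche_genes is None:
        gene_idx = np.arange(ds.n_genes)
        names = ds.gene_names
    else:
        gene_idx = ds.gene_indices(niche_genes)
        names = ds.gene_names[gene_idx]
    neighbors = spatial_knn_indices(ds.coords, k, include_self=include_self)
    expr = ds.counts[:, gene_idx]
    if transform == "log1p":
        expr = np.log1p(expr)
    niche = expr[neighbors]  # (n, k, g')
    return NicheTensor(
        neighbor_indices=neighbors,
        niche_expression=niche,
        niche_genes=np.asarray(names, dtype=object),
        k=k,
        include_self=include_self,
        transform=transform,
    )


def compute_covet(niches: NicheTensor, global_mean="auto") -> CovetSet:
    """Shifted covariance Sigma_i = (1/k)(E_i - Xbar)^T (E_i - Xbar) per cell.

    ``global_mean="auto"`` uses the mean expression over all cells of the
    dataset (same transform as the niches); passing the niche's own column
    means instead recovers the classic covariance.
    """
    E = niches.niche_expression
    if not np.all(np.isfinite(E)):
        raise ValueError("niche expression contains non-finite values")
    n, k, g = E.shape
    if isinstance(global_mean, str) and global_mean == "auto":
        # mean over the underlying cells, not over niche slots, so each cell
        # contributes once regardless of how many niches it appears in
        xbar = _dataset_mean_from_niches(niches)
    else:
        xbar = np.asarray(global_mean, dtype=np.float64)
        if xbar.shape != (g,):
            raise ValueError(f"global_mean must have shape ({g},)")
    centered = E - xbar[None, None, :]
    mats = np.einsum("nkg,nkh->ngh", centered, centered) / k
    sqrts = batch_matrix_sqrt(mats)
    return CovetSet(
        matrices=mats,
        sqrt_matrices=sqrts,
        global_mean=xbar,
        niche_genes=niches.niche_genes,
        k=niches.k,
    )


def _dataset_mean_from_niches(niches: NicheTensor) -> np.ndarray:
    """Dataset-wide mean expression recovered from unique niche members."""
    idx = niches.neighbor_indices
    E = niches.niche_expression
    n_total = int(idx.max()) + 1
    g = E.shape[2]
    seen = np.zeros(n_total, dtype=bool)
    expr = np.zeros((n_total, g))
    flat_idx = idx.ravel()
    expr[flat_idx] = E.reshape(-1, g)
    seen[flat_idx] = True
    if not seen.all():  # cells never appearing as neighbors: fall back to mean of seen
        return expr[seen].mean(axis=0)
    return expr.mean(axis=0)


def covet_from_dataset(
    ds: SpatialDataset,
    k: int = DEFAULT_K,
    niche_genes=None,
    include_self: bool = False,
    transform: str = "raw",
) -> CovetSet:
    """One-call COVET pipeline: niches then shifted covariances + MSQRs.

    The shift reference is the dataset-wide mean over *all* cells of ``ds``
    (after the same transform), matching the definition of ShiftCov.
    """
    niches = build_niche_tensor(
        ds, k=k, niche_genes=niche_genes, include_self=include_self, transform=transform
    )
    gene_idx = ds.gene_indices(niches.niche_genes)
    expr = ds.counts[:, gene_idx]
    if transform == "log1p":
        expr = np.log1p(expr)
    return compute_covet(niches, global_mean=expr.mean(axis=0))


def highly_variable_panel_genes(ds: SpatialDataset, n_top: int = 64) -> np.ndarray:
    """Top dispersion-ranked panel genes, the default COVET gene subset."""
    expr = np.log1p(ds.counts)
    mean = expr.mean(axis=0)
    var = expr.var(axis=0)
    dispersion = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    order = np.argsort(-dispersion, kind="stable")[: min(n_top, ds.n_genes)]
    order.sort()
    return ds.gene_names[order]


# ---------------------------------------------------------------------------
# matrix square roots and metrics


def _check_symmetric(S: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"expected a square matrix, got {S.shape}")
    scale = max(np.abs(S).max(), 1.0)
    if np.abs(S - S.T).max() > tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    return 0.5 * (S + S.T)


def matrix_sqrt(S: np.ndarray, clip_tol: float = 1e-12) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition.

    Eigenvalues below ``clip_tol * max(eigenvalue)`` (negative round-off
    included) are clipped to zero, so slightly indefinite inputs from
    floating-point noise are handled gracefully.
    """
    S = _check_symmetric(S)
    w, V = np.linalg.eigh(S)
    w = np.where(w > clip_tol * max(w.max(), 0.0), w, 0.0)
    return (V * np.sqrt(w)) @ V.T


def batch_matrix_sqrt(mats: np.ndarray, clip_tol: float = 1e-12) -> np.ndarray:
    """Vectorized symmetric square roots of a stack of PSD matrices."""
    mats = np.asarray(mats, dtype=np.float64)
    sym = 0.5 * (mats + np.swapaxes(mats, -1, -2))
    w, V = np.linalg.eigh(sym)
    top = np.maximum(w[..., -1:], 0.0)
    w = np.where(w > clip_tol * top, w, 0.0)
    return np.einsum("...ij,...j,...kj->...ik", V, np.sqrt(w), V)


def frechet_distance(Sa: np.ndarray, Sb: np.ndarray) -> float:
    """Exact Frechet (Bures-Wasserstein) distance between PSD matrices.

    Tr A + Tr B - 2 Tr (A^1/2 B A^1/2)^1/2, computed in the symmetrized
    form (numerically stabler than rooting the possibly non-symmetric
    product AB, with the same trace for PSD inputs). Tiny negative round-off
    is clipped at zero.
    """
    Sa = _check_symmetric(Sa)
    Sb = _check_symmetric(Sb)
    if Sa.shape != Sb.shape:
        raise ValueError("matrices must share a shape")
    Ra = matrix_sqrt(Sa)
    inner = matrix_sqrt(Ra @ Sb @ Ra)
    val = np.trace(Sa) + np.trace(Sb) - 2.0 * np.trace(inner)
    return float(max(val, 0.0))


def aot_distance(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """AOT distance between two matrix square roots: ||Ra - Rb||_F.

    The squared value equals Tr A + Tr B - 2 Tr(Ra Rb), the swapped-trace
    approximation of the Frechet distance; when A and B commute the two
    coincide exactly.
    """
    Ra = np.asarray(Ra, dtype=np.float64)
    Rb = np.asarray(Rb, dtype=np.float64)
    if Ra.shape != Rb.shape:
        raise ValueError("matrices must share a shape")
    return float(np.linalg.norm(Ra - Rb))

def pairwise_aot(covets: CovetSet) -> DistanceMatrix:
    """All-pairs AOT distances as Euclidean distance on flattened MSQRs."""
    flat = covets.flattened_sqrts()
    if flat.shape[0] < 2:
        raise ValueError("need at least two cells")
    from scipy.spatial.distance import pdist, squareform

    vals = squareform(pdist(flat, metric="euclidean"))
    return DistanceMatrix(values=vals, metric_name="aot")


def bhattacharyya_distance(
    Sa: np.ndarray, Sb: np.ndarray, ridge: float | None = None
) -> float:
    """Bhattacharyya distance between zero-mean Gaussians with the given covariances.

    0.5 * ln( det((A+B)/2) / sqrt(det A det B) ), after adding a ridge
    ``eps * I`` (default ``1e-6 * mean(diag)``) so rank-deficient COVET
    matrices stay in the domain of the determinant.
    """
    Sa = _check_symmetric(Sa)
    Sb = _check_symmetric(Sb)
    if Sa.shape != Sb.shape:
        raise ValueError("matrices must share a shape")
    if ridge is None:
        ridge = 1e-6 * max(0.5 * (np.trace(Sa) + np.trace(Sb)) / Sa.shape[0], 1e-12)
    eye = ridge * np.eye(Sa.shape[0])
    A = Sa + eye
    B = Sb + eye
    sign_m, logdet_m = np.linalg.slogdet(0.5 * (A + B))
    sign_a, logdet_a = np.linalg.slogdet(A)
    sign_b, logdet_b = np.linalg.slogdet(B)
    if min(sign_m, sign_a, sign_b) <= 0:
        raise np.linalg.LinAlgError("covariance singular after regularization")
    return float(0.5 * (logdet_m - 0.5 * (logdet_a + logdet_b)))


def covet_mean(sqrt_matrices: np.ndarray) -> np.ndarray:
    """AOT (Bures) average of a set of COVET matrices from their MSQRs.

    The mean of the square roots, squared: the Frechet mean under the AOT
    metric. Accepts an (m, g, g) stack of MSQRs; symmetric PSD output.
    """
    R = np.asarray(sqrt_matrices, dtype=np.float64)
    if R.ndim != 3 or R.shape[0] == 0:
        raise ValueError("need a non-empty (m, g, g) stack of square roots")
    mean_R = R.mean(axis=0)
    mean_R = 0.5 * (mean_R + mean_R.T)
    return mean_R @ mean_R


# ---------------------------------------------------------------------------
# diffusion components


def diffusion_components(
    vectors: np.ndarray,
    k: int = 30,
    n_components: int = 3,
) -> np.ndarray:
    """Leading non-trivial diffusion components of a kNN graph on ``vectors``.

    Builds a kNN graph (Gaussian kernel; global bandwidth set to the median
    distance to the ceil(k/2)-th neighbor), symmetrizes by elementwise max,
    row-normalizes to a transition matrix and returns the ``n_components``
    leading non-trivial eigenvectors ordered by decreasing eigenvalue. Used
    on flattened COVET MSQRs (where Euclidean distance is the AOT metric)
    the first component serves as a pseudo-spatial axis.

    The sign of each component is fixed so its correlation with the first
    input feature is non-negative (eigenvector signs are arbitrary).
    """
    X = np.asarray(vectors, dtype=np.float64)
    m = X.shape[0]
    if k >= m:
        raise ValueError(f"k={k} must be smaller than the number of points {m}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    bw = max(float(np.median(dist[:, int(np.ceil(k / 2)) - 1])), 1e-12)
    w = np.exp(-(dist**2) / bw**2)
    rows = np.repeat(np.arange(m), k)
    W = sp.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(m, m))
    W = W.maximum(W.T)
    deg = np.asarray(W.sum(axis=1)).ravel()
    deg = np.maximum(deg, 1e-300)
    # symmetric conjugate of the row-normalized transition matrix
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    M = d_inv_sqrt @ W @ d_inv_sqrt
    n_eigs = min(n_components + 1, m - 1)
    vals, vecs = eigsh(M, k=n_eigs, which="LA")
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    # map back to right eigenvectors of the transition matrix; drop trivial
    vecs = vecs / np.sqrt(deg)[:, None]
    dcs = vecs[:, 1 : n_components + 1]
    dcs = dcs * vals[1 : n_components + 1][None, :]
    feat = X[:, 0]
    for j in range(dcs.shape[1]):
        c = np.corrcoef(dcs[:, j], feat)[0, 1] if np.std(feat) > 0 else 1.0
        if np.isfinite(c) and c < 0:
            dcs[:, j] = -dcs[:, j]
    return dcs
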