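"""Dataset containers for the spatial and dissociated modalities.

Both containers hold raw, non-negative count matrices. The spatial container
additionally carries per-cell coordinates (2-D or 3-D, arbitrary length
units). Gene names are matched case-insensitively across modalities; the
spatial panel must be a subset of the single-cell gene list for joint
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


def _as_dense(counts) -> np.ndarray:
    if sp.issparse(counts):
        counts = counts.toarray()
    arr = np.asarray(counts, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"counts must be 2-D, got shape {arr.shape}")
    return arr


def _check_counts(counts: np.ndarray) -> None:
    if not np.all(np.isfinite(counts)):
        raise ValueError("counts contain non-finite values")
    if counts.min(initial=0.0) < 0:
        raise ValueError("counts must be non-negative")


def _check_names(gene_names, n_genes: int) -> np.ndarray:
    names = np.asarray(gene_names, dtype=object)
    if names.shape != (n_genes,):
        raise ValueError(
            f"gene_names has length {names.shape}, expected ({n_genes},)"
        )
    lowered = pd.Index([str(g).lower() for g in names])
    if lowered.has_duplicates:
        dupes = lowered[lowered.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene names (case-insensitive): {dupes}")
    return names


@dataclass
class SpatialDataset:
    """Segmented spatial transcriptomics profiles with coordinates.

    Parameters
    ----------
    counts
        ``(n_cells, n_genes)`` non-negative count matrix (dense or sparse).
    coords
        ``(n_cells, d)`` spatial coordinates, ``d`` in {2, 3}.
    gene_names
        Unique identifiers for the imaged gene panel.
    labels
        Optional per-cell categorical annotation (e.g. cell type).
    """

    counts: np.ndarray
    coords: np.ndarray
    gene_names: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = _as_dense(self.counts)
        _check_counts(self.counts)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError(
                f"coords must be (n, 2) or (n, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] != self.counts.shape[0]:
            raise ValueError("counts and coords disagree on cell number")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        self.gene_names = _check_names(self.gene_names, self.counts.shape[1])
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n_cells:
                raise ValueError("labels length does not match cell number")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_indices(self, genes) -> np.ndarray:
        """Panel indices of ``genes`` (case-insensitive); unknown name raises KeyError."""
        lookup = {str(g).lower(): i for i, g in enumerate(self.gene_names)}
        idx = []
        for g in genes:
            key = str(g).lower()
            if key not in lookup:
                raise KeyError(f"gene {g!r} not in panel")
            idx.append(lookup[key])
        return np.asarray(idx, dtype=np.intp)


@dataclass
class SingleCellDataset:
    """Dissociated scRNA-seq profiles over a transcriptome-scale gene list."""

    counts: np.ndarray
    gene_names: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = _as_dense(self.counts)
        _check_counts(self.counts)
        self.gene_names = _check_names(self.gene_names, self.counts.shape[1])
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n_cells:
                raise ValueError("labels length does not match cell number")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_indices(self, genes) -> np.ndarray:
        lookup = {str(g).lower(): i for i, g in enumerate(self.gene_names)}
        idx = []
        missing = [g for g in genes if str(g).lower() not in lookup]
        if missing:
            raise KeyError(f"genes absent from single-cell data: {missing}")
        for g in genes:
            idx.append(lookup[str(g).lower()])
        return np.asarray(idx, dtype=np.intp)


def match_panel(spatial: SpatialDataset, sc: SingleCellDataset) -> np.ndarray:
    """Indices into ``sc.gene_names`` for the spatial panel, in panel order.

    Matching is case-insensitive; raises ``KeyError`` listing any panel gene
    absent from the single-cell data.
    """
    return sc.gene_indices(spatial.gene_names)
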