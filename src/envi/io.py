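"""Readers and writers for the supported on-disk formats.

Counts move through h5ad (AnnData), CSV/TSV (cells x genes with an optional
two-column coordinate file) or MTX triplets with row/column name files.
Outputs follow fixed key conventions so downstream tools can rely on them:
imputed expression in the layer ``"envi_imputed"``, flattened inferred
MSQRs in ``obsm["envi_covet_sqrt"]`` and latent means in
``obsm["envi_latent"]``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .data import SingleCellDataset, SpatialDataset

IMPUTED_LAYER = "envi_imputed"
COVET_SQRT_KEY = "envi_covet_sqrt"
LATENT_KEY = "envi_latent"
DEFAULT_COORD_KEY = "spatial"


def _counts_from_adata(adata: ad.AnnData, layer: str | None) -> np.ndarray:
    X = adata.layers[layer] if layer else adata.X
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def load_dataset(
    path,
    format: str | None = None,
    coord_key: str = DEFAULT_COORD_KEY,
    coords_path=None,
    layer: str | None = None,
    spatial: bool | None = None,
):
    """Read a dataset; returns SpatialDataset if coordinates are found.

    ``format`` in {"h5ad", "csv", "mtx"}; inferred from the suffix when
    omitted. For CSV/TSV a separate ``coords_path`` (two or three numeric
    columns) marks the dataset as spatial. For h5ad, coordinates are read
    from ``obsm[coord_key]``. ``spatial=True`` insists on coordinates and
    raises a clear error naming the expected key if they are missing.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".h5ad": "h5ad", ".csv": "csv", ".tsv": "csv", ".mtx": "mtx"}.get(
            suffix
        )
        if format is None:
            raise ValueError(f"cannot infer format from {path.name!r}")

    labels = None
    if format == "h5ad":
        adata = ad.read_h5ad(path)
        counts = _counts_from_adata(adata, layer)
        genes = adata.var_names.to_numpy(dtype=object)
        if "labels" in adata.obs:
            labels = adata.obs["labels"].to_numpy()
        coords = adata.obsm.get(coord_key)
    elif format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, index_col=0, sep=sep)
        bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
        if len(bad):
            raise ValueError(f"non-numeric columns in {path.name}: {list(bad)}")
        counts = df.to_numpy(dtype=np.float64)
        genes = df.columns.to_numpy(dtype=object)
        coords = None
        if coords_path is not None:
            cdf = pd.read_csv(coords_path, index_col=0)
            coords = cdf.to_numpy(dtype=np.float64)
    elif format == "mtx":
        counts = sio.mmread(path)
        counts = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
        rows = pd.read_csv(path.with_suffix(".rows.txt"), header=None)[0]
        cols = pd.read_csv(path.with_suffix(".cols.txt"), header=None)[0]
        if counts.shape != (len(rows), len(cols)):
            raise ValueError("MTX shape disagrees with row/column name files")
        genes = cols.to_numpy(dtype=object)
        coords = None
        cpath = path.with_suffix(".coords.csv")
        if cpath.exists():
            coords = pd.read_csv(cpath, index_col=0).to_numpy(dtype=np.float64)
    else:
        raise ValueError(f"unknown format {format!r}")

    if coords is not None:
        return SpatialDataset(counts=counts, coords=np.asarray(coords),
                              gene_names=genes, labels=labels)
    if spatial:
        raise ValueError(
            f"spatial dataset requested but no coordinates found "
            f"(expected obsm key {coord_key!r} or a coordinate file)"
        )
    return SingleCellDataset(counts=counts, gene_names=genes, labels=labels)


def to_anndata(ds) -> ad.AnnData:
    adata = ad.AnnData(X=ds.counts.copy())
    adata.var_names = [str(g) for g in ds.gene_names]
    if getattr(ds, "labels", None) is not None:
        adata.obs["labels"] = ds.labels
    if isinstance(ds, SpatialDataset):
        adata.obsm[DEFAULT_COORD_KEY] = ds.coords.copy()
    return adata


def save_dataset(ds, path) -> None:
    """Write a dataset as h5ad or CSV (+ coords CSV for spatial data)."""
    path = Path(path)
    if path.suffix.lower() == ".h5ad":
        to_anndata(ds).write_h5ad(path)
        return
    df = pd.DataFrame(
        ds.counts,
        columns=[str(g) for g in ds.gene_names],
        index=[f"cell_{i}" for i in range(ds.n_cells)],
    )
    df.to_csv(path)
    if isinstance(ds, SpatialDataset):
        cdf = pd.DataFrame(
            ds.coords,
            columns=["x", "y", "z"][: ds.coords.shape[1]],
            index=df.index,
        )
        cdf.to_csv(path.with_suffix(".coords.csv"))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_results(bundle: dict, out_dir) -> dict:
    """Persist a result bundle and return a manifest with content hashes.

    ``bundle`` maps file names to objects: AnnData (written as h5ad),
    DataFrame (CSV), numpy arrays (NPZ under the given name), and plain
    dicts (JSON/YAML by suffix). A ``.partial`` marker guards interrupted
    writes and is removed only after the file closes cleanly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}}
    for name, obj in bundle.items():
        target = out_dir / name
        marker = target.with_suffix(target.suffix + ".partial")
        marker.touch()
        try:
            if isinstance(obj, ad.AnnData):
                obj.write_h5ad(target)
            elif isinstance(obj, pd.DataFrame):
                obj.to_csv(target)
            elif isinstance(obj, np.ndarray):
                np.savez_compressed(target, data=obj)
            elif isinstance(obj, dict):
                if target.suffix in (".yaml", ".yml"):
                    import yaml

                    with open(target, "w") as fh:
                        yaml.safe_dump(obj, fh)
                else:
                    with open(target, "w") as fh:
                        json.dump(obj, fh, indent=2, default=str)
            else:
                raise TypeError(f"cannot serialize {type(obj)} for {name!r}")
        finally:
            if target.exists():
                marker.unlink(missing_ok=True)
        manifest["files"][name] = _sha256(target)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
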