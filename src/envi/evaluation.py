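"""Cross-validation harness and metrics for imputation and label transfer.

Held-out genes are scored on log expression with pseudocount 0.1 via
Pearson correlation (per-cell agreement) and MSSI (spatially aware
agreement). Cross-modality label transfer is scored with balanced accuracy
(macro-averaged per-class recall), which is robust to unbalanced cell-type
proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .data import SingleCellDataset, SpatialDataset
from .mssi import MssiConfig, mssi
from .model import EnviConfig, train

LOG_PSEUDOCOUNT = 0.1


@dataclass
class FoldPlan:
    """Disjoint, exhaustive partition of the spatial panel into gene folds."""

    folds: list  # list of arrays of gene names
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        flat = [g for fold in self.folds for g in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds overlap")


def make_folds(panel_genes, scheme: str = "kfold:5", seed: int = 0) -> FoldPlan:
    """Random balanced gene partition: ``"kfold:F"`` or ``"loo"`` (leave-one-out)."""
    genes = np.asarray(panel_genes, dtype=object)
    if scheme == "loo":
        n_folds = genes.size
    elif scheme.startswith("kfold:"):
        n_folds = int(scheme.split(":", 1)[1])
        if n_folds > genes.size:
            raise ValueError(
                f"{n_folds} folds requested for {genes.size} genes"
            )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(genes.size)
    folds = [genes[np.sort(part)] for part in np.array_split(perm, n_folds)]
    return FoldPlan(folds=folds, scheme=scheme, seed=seed)


def pearson_log(truth: np.ndarray, imputed: np.ndarray) -> float:
    """Pearson correlation of log(x + 0.1) profiles; NaN if either is constant."""
    a = np.log(np.asarray(truth, dtype=np.float64) + LOG_PSEUDOCOUNT)
    b = np.log(np.asarray(imputed, dtype=np.float64) + LOG_PSEUDOCOUNT)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def imputation_scores(
    truth: np.ndarray,
    imputed: np.ndarray,
    coords: np.ndarray,
    gene_names,
    mssi_config: MssiConfig | None = None,
) -> dict:
    """Per-gene ``{"pearson_log": ..., "mssi": ...}`` for matched matrices.

    Zero-variance genes yield ``pearson_log = nan`` (reported, never
    silently zero). MSSI is computed on the log-pseudocount profiles over
    the provided coordinates.
    """
    truth = np.asarray(truth, dtype=np.float64)
    imputed = np.asarray(imputed, dtype=np.float64)
    if truth.shape != imputed.shape:
        raise ValueError("truth and imputed must share a shape")
    scores = {}
    for j, g in enumerate(gene_names):
        t = np.log(truth[:, j] + LOG_PSEUDOCOUNT)
        p = np.log(imputed[:, j] + LOG_PSEUDOCOUNT)
        scores[str(g)] = {
            "pearson_log": pearson_log(truth[:, j], imputed[:, j]),
            "mssi": mssi(t, p, coords, mssi_config),
        }
    return scores


def balanced_accuracy(true_labels, predicted_labels) -> float:
    """Macro-averaged per-class recall over the classes present in the truth.

    Predicted classes absent from the truth are excluded with a warning.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must share a length")
    classes = np.unique(true_labels)
    extra = np.setdiff1d(np.unique(predicted_labels), classes)
    if extra.size:
        warnings.warn(
            f"predicted classes absent from the truth are ignored: {extra.tolist()}"
        )
    recalls = [
        np.mean(predicted_labels[true_labels == c] == c) for c in classes
    ]
    return float(np.mean(recalls))


def knn_label_transfer(
    ref_vectors: np.ndarray,
    ref_labels,
    query_vectors: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """Majority vote among the k Euclidean nearest reference vectors.

    Vote ties are broken in favor of the candidate class with the smallest
    mean distance among the tied classes' supporting neighbors.
    """
    ref_vectors = np.asarray(ref_vectors, dtype=np.float64)
    ref_labels = np.asarray(ref_labels)
    if ref_vectors.shape[0] == 0:
        raise ValueError("empty reference")
    if k > ref_vectors.shape[0]:
        raise ValueError("k exceeds the reference size")
    nn = NearestNeighbors(n_neighbors=k).fit(ref_vectors)
    dists, idx = nn.kneighbors(np.asarray(query_vectors, dtype=np.float64))
    out = np.empty(idx.shape[0], dtype=ref_labels.dtype)
    for i in range(idx.shape[0]):
        labels = ref_labels[idx[i]]
        cand, counts = np.unique(labels, return_counts=True)
        top = cand[counts == counts.max()]
        if top.size == 1:
            out[i] = top[0]
        else:
            mean_d = [dists[i][labels == c].mean() for c in top]
            out[i] = top[int(np.argmin(mean_d))]
    return out


def paired_onesided_t(scores_a, scores_b) -> float:
    """One-sided paired t-test p-value for mean(a) > mean(b) across genes.

    Returns 0.5 for identical score vectors (no evidence either way).
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    diff = a - b
    if np.allclose(diff, 0):
        return 0.5
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.pvalue)


def cross_validate_imputation(
    spatial: SpatialDataset,
    sc: SingleCellDataset,
    config: EnviConfig | None = None,
    scheme: str = "kfold:5",
    seed: int = 0,
    mssi_config: MssiConfig | None = None,
) -> dict:
    """Hold out gene folds, retrain on the reduced panel, score imputations.

    For each fold the held-out genes are removed from the spatial panel
    (and hence from the encoder input) and the model is retrained from
    scratch; predictions are assembled so every panel gene is scored
    exactly once against its measured expression.
    """
    if config is None:
        config = EnviConfig()
    plan = make_folds(spatial.gene_names, scheme=scheme, seed=seed)
    all_scores: dict = {}
    for fold in plan.folds:
        held = set(str(g).lower() for g in fold)
        keep = np.array(
            [str(g).lower() not in held for g in spatial.gene_names]
        )
        reduced = SpatialDataset(
            counts=spatial.counts[:, keep],
            coords=spatial.coords,
            gene_names=spatial.gene_names[keep],
            labels=spatial.labels,
        )
        model = train(reduced, sc, config)
        imputed_full = model.impute_genes(reduced.counts)
        sc_name_to_col = {
            str(g).lower(): j for j, g in enumerate(model.sc_gene_names)
        }
        held_idx = spatial.gene_indices(list(fold))
        truth = spatial.counts[:, held_idx]
        cols = [sc_name_to_col[str(g).lower()] for g in fold]
        pred = imputed_full[:, cols]
        all_scores.update(
            imputation_scores(truth, pred, spatial.coords, fold, mssi_config)
        )
    return all_scores
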