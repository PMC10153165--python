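"""Seeded synthetic tissues and benchmark generators.

``generate_tissue`` emulates a paired spatial / dissociated experiment:
cells in the unit square organized into horizontal zone bands (mimicking
laminar tissue such as cortical layers), per-zone gene programs whose
activities transition smoothly (logistically) across the band axis, two
opposing continuous gradient programs spanning the whole band axis (the
analog of axial morphogen gradients, so niche structure varies smoothly as
well as discretely), a small imaged panel observed under Poisson noise,
and a transcriptome-scale single-cell set observed under negative-binomial
noise. Each program's marker genes are strided across the gene list, so
the imaged panel contains markers of every program, as a designed FISH
panel would. A designated group
of unimaged genes exactly duplicates imaged genes' rates, giving imputation
a known ground truth; every single-cell profile shares its generative state
(location, program activity, rates) with a spatial cell of the same index,
which gives niche-inference a matched-pair oracle.

``random_covariance_set`` and ``random_count_datasets`` reproduce the
random benchmark inputs used to stress the niche metrics and the trainer:
Gramians of standard-normal matrices (64 x 64 by default), and iid
Poisson(10) spatial / NB(r=10, p=0.8) single-cell count tables whose first
128 genes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SingleCellDataset, SpatialDataset


@dataclass
class SyntheticTruth:
    """Generative ground truth for parameter-recovery tests."""

    coords: np.ndarray  # (n_spatial, 2)
    zone_labels: np.ndarray  # (n_spatial,) int
    program_activity: np.ndarray  # (n_spatial, n_zones)
    rates: np.ndarray  # (n_spatial, g_total) noiseless expression rates
    sc_rates: np.ndarray  # (n_sc, g_total)
    sc_coords: np.ndarray  # latent positions of the dissociated cells
    sc_zone_labels: np.ndarray
    panel_indices: np.ndarray  # imaged subset of the g_total genes
    duplicate_map: dict  # unimaged gene index -> duplicated panel gene index
    matched_pairs: int  # sc cell i < matched_pairs shares state with spatial cell i
    generator_params: dict


def _program_activity(
    band: np.ndarray,
    n_zones: int,
    transition: float,
    rng,
    noise: float,
    gradient_strength: float,
) -> np.ndarray:
    """Per-cell activities of the n_zones + 2 programs along the band axis.

    Zone p is a logistic bump between consecutive band boundaries; the two
    extra programs are opposing linear gradients spanning the axis.
    Gaussian noise is added and activities clipped at zero.
    """
    edges = np.linspace(0.0, 1.0, n_zones + 1)
    act = np.empty((band.size, n_zones + 2))
    for p in range(n_zones):
        lo, hi = edges[p], edges[p + 1]
        rise = 1.0 / (1.0 + np.exp(-(band - lo) / transition))
        fall = 1.0 / (1.0 + np.exp(-(band - hi) / transition))
        act[:, p] = rise - fall
    act[:, n_zones] = gradient_strength * band
    act[:, n_zones + 1] = gradient_strength * (1.0 - band)
    act += rng.normal(0.0, noise, size=act.shape)
    return np.clip(act, 0.0, None)


def generate_tissue(
    n_spatial: int = 2000,
    n_sc: int = 2000,
    g_panel: int = 64,
    g_total: int = 256,
    n_zones: int = 4,
    seed: int = 0,
    mean_rate: float = 4.0,
    baseline_rate: float = 0.2,
    transition: float = 0.03,
    activity_noise: float = 0.05,
    nb_dispersion: float = 4.0,
    n_duplicates: int = 8,
    gradient_strength: float = 2.0,
):
    """Paired synthetic spatial + single-cell datasets with known truth.

    Returns ``(SpatialDataset, SingleCellDataset, SyntheticTruth)``. The
    first ``min(n_spatial, n_sc)`` single-cell profiles are re-draws (under
    NB noise) of the same generative state as the spatial cells with the
    same index; extra cells on either side are drawn fresh.
    """
    if g_panel >= g_total:
        raise ValueError("g_panel must be smaller than g_total")
    if n_zones < 2:
        raise ValueError("need at least two zones")
    if n_spatial < 2 or n_sc < 1:
        raise ValueError("need at least two spatial cells and one sc cell")
    rng = np.random.default_rng(seed)

    coords = rng.uniform(0.0, 1.0, size=(n_spatial, 2))
    band = coords[:, 1]  # zones are horizontal bands: y is the band axis
    zone_labels = np.minimum((band * n_zones).astype(int), n_zones - 1)
    activity = _program_activity(
        band, n_zones, transition, rng, activity_noise, gradient_strength
    )
    n_programs = n_zones + 2

    # non-negative loading matrix: each program strongly drives a strided
    # subset of genes (so the imaged panel sees markers of every program)
    # plus dense low-level crosstalk so covariances are informative
    loading = rng.gamma(shape=0.4, scale=0.5, size=(n_programs, g_total))
    for p in range(n_programs):
        strong = np.arange(p, g_total, n_programs)
        loading[p, strong] += rng.gamma(shape=2.0, scale=1.5, size=strong.size)
    scale = mean_rate / max((activity @ loading).mean(), 1e-9)
    panel_indices = np.arange(g_panel)

    # unimaged duplicates of imaged genes: exact imputation ground truth
    n_dup = min(n_duplicates, g_total - g_panel, g_panel)
    dup_targets = rng.choice(g_panel, size=n_dup, replace=False)
    duplicate_map = {}
    for j, tgt in enumerate(dup_targets):
        unimaged = g_panel + j
        loading[:, unimaged] = loading[:, tgt]
        duplicate_map[int(unimaged)] = int(tgt)

    rates = scale * (activity @ loading) + baseline_rate

    matched = min(n_spatial, n_sc)
    if n_sc > matched:
        extra_coords = rng.uniform(0.0, 1.0, size=(n_sc - matched, 2))
        extra_band = extra_coords[:, 1]
        extra_act = _program_activity(
            extra_band, n_zones, transition, rng, activity_noise, gradient_strength
        )
        sc_coords = np.vstack([coords[:matched], extra_coords])
        sc_act = np.vstack([activity[:matched], extra_act])
    else:
        sc_coords = coords[:matched].copy()
        sc_act = activity[:matched].copy()
    sc_rates = scale * (sc_act @ loading) + baseline_rate
    sc_band = sc_coords[:, 1]
    sc_zones = np.minimum((sc_band * n_zones).astype(int), n_zones - 1)

    spatial_counts = rng.poisson(rates[:, panel_indices]).astype(np.float64)
    # NB(r, p) with mean mu: p = r / (r + mu)
    p_nb = nb_dispersion / (nb_dispersion + sc_rates)
    sc_counts = rng.negative_binomial(nb_dispersion, p_nb).astype(np.float64)

    gene_names = np.array([f"gene_{j:04d}" for j in range(g_total)], dtype=object)
    spatial = SpatialDataset(
        counts=spatial_counts,
        coords=coords,
        gene_names=gene_names[panel_indices],
        labels=zone_labels.astype(str),
    )
    sc = SingleCellDataset(
        counts=sc_counts,
        gene_names=gene_names,
        labels=sc_zones.astype(str),
    )
    truth = SyntheticTruth(
        coords=coords,
        zone_labels=zone_labels,
        program_activity=activity,
        rates=rates,
        sc_rates=sc_rates,
        sc_coords=sc_coords,
        sc_zone_labels=sc_zones,
        panel_indices=panel_indices,
        duplicate_map=duplicate_map,
        matched_pairs=matched,
        generator_params={
            "n_spatial": n_spatial,
            "n_sc": n_sc,
            "g_panel": g_panel,
            "g_total": g_total,
            "n_zones": n_zones,
            "seed": seed,
            "mean_rate": mean_rate,
            "baseline_rate": baseline_rate,
            "transition": transition,
            "activity_noise": activity_noise,
            "nb_dispersion": nb_dispersion,
            "gradient_strength": gradient_strength,
        },
    )
    return spatial, sc, truth


def random_covariance_set(n: int, g: int = 64, seed: int = 0) -> np.ndarray:
    """``n`` random ``g x g`` PSD matrices: Gramians X X^T of standard normals."""
    if n < 1 or g < 1:
        raise ValueError("n and g must be positive")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, g, g))
    return X @ np.swapaxes(X, -1, -2)


def random_count_datasets(m: int, seed: int = 0):
    """Random runtime-benchmark inputs: Poisson(10) spatial counts over 128
    genes and NB(r=10, p=0.8) single-cell counts over 2048 genes, with genes
    named by order so the first 128 single-cell genes form the spatial panel."""
    if m < 1:
        raise ValueError("m must be positive")
    rng = np.random.default_rng(seed)
    st_counts = rng.poisson(10.0, size=(m, 128)).astype(np.float64)
    sc_counts = rng.negative_binomial(10, 0.8, size=(m, 2048)).astype(np.float64)
    genes = np.array([f"gene_{j:04d}" for j in range(2048)], dtype=object)
    # random scatter for coordinates: the benchmark only exercises runtime
    coords = rng.uniform(0.0, 1.0, size=(m, 2))
    spatial = SpatialDataset(counts=st_counts, coords=coords, gene_names=genes[:128])
    sc = SingleCellDataset(counts=sc_counts, gene_names=genes)
    return spatial, sc
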