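"""Unit tests for niche construction, shifted covariances and the metrics."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from envi.covet import (
    NicheTensor,
    aot_distance,
    bhattacharyya_distance,
    build_niche_tensor,
    compute_covet,
    covet_from_dataset,
    covet_mean,
    diffusion_components,
    frechet_distance,
    matrix_sqrt,
    pairwise_aot,
    spatial_knn_indices,
)
from envi.data import SpatialDataset
from envi.synthetic import random_covariance_set


def _niche(E, k=None):
    E = np.asarray(E, dtype=np.float64)[None]
    k = k or E.shape[1]
    return NicheTensor(
        neighbor_indices=np.zeros((1, E.shape[1]), dtype=np.intp),
        niche_expression=E,
        niche_genes=np.array([f"g{i}" for i in range(E.shape[2])], dtype=object),
        k=k,
        include_self=False,
    )


class TestNicheConstruction:
    def test_two_cells_mutual_neighbors(self):
        ds = SpatialDataset(
            counts=np.ones((2, 1)),
            coords=np.array([[0.0, 0.0], [1.0, 0.0]]),
            gene_names=np.array(["g"], dtype=object),
        )
        nt = build_niche_tensor(ds, k=1)
        assert nt.neighbor_indices[0, 0] == 1
        assert nt.neighbor_indices[1, 0] == 0

    def test_grid_center_neighbors_match_bruteforce(self, grid_dataset):
        coords = grid_dataset.coords
        center = 12  # (2, 2) on the 5x5 grid
        nt = build_niche_tensor(grid_dataset, k=4)
        # oracle: sort all candidate distances by (distance, index)
        d = np.linalg.norm(coords - coords[center], axis=1)
        order = np.lexsort((np.arange(25), d))
        expected = [i for i in order if i != center][:4]
        assert sorted(nt.neighbor_indices[center]) == sorted(expected)
        # the four orthogonal neighbors sit at distance 1 < sqrt(2)
        assert np.allclose(
            np.sort(np.linalg.norm(coords[expected] - coords[center], axis=1)), 1.0
        )

    def test_default_k_is_8(self, small_tissue):
        st, _, _ = small_tissue
        nt = build_niche_tensor(st)
        assert nt.k == 8
        assert nt.neighbor_indices.shape == (st.n_cells, 8)

    def test_self_excluded_by_default(self, small_tissue):
        st, _, _ = small_tissue
        nt = build_niche_tensor(st, k=5)
        rows = np.arange(st.n_cells)[:, None]
        assert not np.any(nt.neighbor_indices == rows)

    def test_include_self_puts_focal_cell_first(self, grid_dataset):
        nt = build_niche_tensor(grid_dataset, k=3, include_self=True)
        assert np.all(nt.neighbor_indices[:, 0] == np.arange(25))

    def test_k_too_large_raises(self, grid_dataset):
        with pytest.raises(ValueError):
            build_niche_tensor(grid_dataset, k=25)

    def test_unknown_gene_raises(self, grid_dataset):
        with pytest.raises(KeyError):
            build_niche_tensor(grid_dataset, k=2, niche_genes=["nope"])

    def test_duplicate_coordinate_ties_deterministic(self):
        coords = np.zeros((4, 2))  # all coincident: ties broken by index
        ds = SpatialDataset(
            counts=np.ones((4, 1)),
            coords=coords,
            gene_names=np.array(["g"], dtype=object),
        )
        idx = spatial_knn_indices(coords, k=2)
        assert idx.tolist() == [[1, 2], [0, 2], [0, 1], [0, 1]]


class TestComputeCovet:
    def test_worked_example(self):
        cs = compute_covet(_niche([[1.0, 0.0], [3.0, 2.0]]), np.array([1.0, 1.0]))
        assert np.allclose(cs.matrices[0], [[2.0, 1.0], [1.0, 1.0]])

    def test_entrywise_bruteforce_oracle(self, rng):
        E = rng.poisson(5.0, size=(6, 4)).astype(float)
        xbar = rng.uniform(0, 5, size=4)
        cs = compute_covet(_niche(E), xbar)
        k = E.shape[0]
        expected = np.zeros((4, 4))
        for a in range(4):
            for b in range(4):
                expected[a, b] = sum(
                    (E[i, a] - xbar[a]) * (E[i, b] - xbar[b]) for i in range(k)
                ) / k
        assert np.allclose(cs.matrices[0], expected)

    def test_reduces_to_classic_covariance_at_niche_mean(self, rng):
        E = rng.normal(size=(8, 3))
        cs = compute_covet(_niche(E), E.mean(axis=0))
        classic = (E - E.mean(axis=0)).T @ (E - E.mean(axis=0)) / 8
        assert np.allclose(cs.matrices[0], classic)

    def test_rows_equal_to_mean_give_zero_matrix(self):
        E = np.tile([2.0, 3.0], (5, 1))
        cs = compute_covet(_niche(E), np.array([2.0, 3.0]))
        assert np.allclose(cs.matrices[0], 0.0)

    def test_all_outputs_psd_and_sqrt_consistent(self, small_tissue):
        st, _, _ = small_tissue
        cs = covet_from_dataset(st, k=6)
        eigs = np.linalg.eigvalsh(cs.matrices)
        assert eigs.min() >= -1e-8
        recon = cs.sqrt_matrices @ cs.sqrt_matrices
        err = np.linalg.norm(recon - cs.matrices, axis=(1, 2))
        scale = np.linalg.norm(cs.matrices, axis=(1, 2)) + 1e-12
        assert np.all(err / scale < 1e-8)

    def test_nonfinite_input_rejected(self):
        E = np.full((3, 2), np.nan)
        with pytest.raises(ValueError):
            compute_covet(_niche(E), np.zeros(2))


class TestMatrixSqrt:
    def test_identity_and_diagonal_closed_form(self):
        assert np.allclose(matrix_sqrt(np.eye(3)), np.eye(3))
        assert np.allclose(matrix_sqrt(np.diag([4.0, 9.0])), np.diag([2.0, 3.0]))

    def test_reconstructs_random_gramian(self, rng):
        X = rng.standard_normal((5, 5))
        G = X @ X.T
        R = matrix_sqrt(G)
        assert np.linalg.norm(R @ R - G) / np.linalg.norm(G) < 1e-8
        assert np.allclose(R, R.T)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            matrix_sqrt(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestMetrics:
    def test_frechet_zero_on_identical(self, rng):
        S = random_covariance_set(1, 6, seed=1)[0]
        assert frechet_distance(S, S) == pytest.approx(0.0, abs=1e-8)

    def test_frechet_diagonal_closed_form(self):
        # diag(1,4) vs diag(4,1): sum (sqrt(a)-sqrt(b))^2 = 2*(2-1)^2 = 2
        assert frechet_distance(np.diag([1.0, 4.0]), np.diag([4.0, 1.0])) == pytest.approx(2.0)
        assert frechet_distance(np.array([[1.0]]), np.array([[4.0]])) == pytest.approx(1.0)

    def test_aot_examples(self):
        assert aot_distance(np.diag([1.0, 2.0]), np.diag([1.0, 2.0])) == 0.0
        assert aot_distance(np.diag([1.0, 2.0]), np.diag([2.0, 1.0])) == pytest.approx(
            np.sqrt(2.0)
        )

    def test_aot_squared_equals_frechet_for_commuting_pair(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        a = rng.uniform(0.5, 3.0, 6)
        b = rng.uniform(0.5, 3.0, 6)
        Sa = (q * a) @ q.T
        Sb = (q * b) @ q.T
        d2 = aot_distance(matrix_sqrt(Sa), matrix_sqrt(Sb)) ** 2
        assert d2 == pytest.approx(frechet_distance(Sa, Sb), abs=1e-8)

    def test_metric_axioms_on_msqrs(self, rng):
        R = [matrix_sqrt(S) for S in random_covariance_set(4, 5, seed=3)]
        for a in R:
            assert aot_distance(a, a) == 0.0
            for b in R:
                assert aot_distance(a, b) >= 0.0
                assert aot_distance(a, b) == pytest.approx(aot_distance(b, a))
                for c in R:
                    assert aot_distance(a, c) <= aot_distance(a, b) + aot_distance(
                        b, c
                    ) + 1e-12

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            frechet_distance(np.eye(2), np.eye(3))
        with pytest.raises(ValueError):
            aot_distance(np.eye(2), np.eye(3))

    def test_bhattacharyya_scalar_and_symmetry(self):
        # 1-D: 0.5 * ln( ((1+4)/2) / sqrt(1*4) ) = 0.5 * ln 1.25 ~ 0.11157
        val = bhattacharyya_distance(np.array([[1.0]]), np.array([[4.0]]), ridge=0.0)
        assert val == pytest.approx(0.5 * np.log(2.5 / 2.0), rel=1e-6)
        S1, S2 = random_covariance_set(2, 4, seed=5)
        assert bhattacharyya_distance(S1, S2) == pytest.approx(
            bhattacharyya_distance(S2, S1)
        )
        assert bhattacharyya_distance(S1, S1) == pytest.approx(0.0, abs=1e-9)


class TestPairwiseAndMean:
    def test_pairwise_matches_loop_oracle(self, small_tissue):
        st, _, _ = small_tissue
        cs = covet_from_dataset(st, k=5)
        dm = pairwise_aot(cs)
        n = cs.n_cells
        sub = np.arange(0, n, 7)
        for i in sub:
            for j in sub:
                assert dm.values[i, j] == pytest.approx(
                    aot_distance(cs.sqrt_matrices[i], cs.sqrt_matrices[j]), abs=1e-10
                )
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_covet_mean_examples(self, rng):
        S = random_covariance_set(1, 4, seed=9)[0]
        R = matrix_sqrt(S)
        assert np.allclose(covet_mean(np.stack([R, R])), S)
        # 1x1: ((1+3)/2)^2 = 4
        assert covet_mean(np.array([[[1.0]], [[3.0]]]))[0, 0] == pytest.approx(4.0)
        Rs = np.stack([matrix_sqrt(s) for s in random_covariance_set(5, 4, seed=11)])
        out = covet_mean(Rs)
        assert np.allclose(out, out.T)
        assert np.linalg.eigvalsh(out).min() >= -1e-10

    def test_covet_mean_empty_raises(self):
        with pytest.raises(ValueError):
            covet_mean(np.empty((0, 3, 3)))


class TestDiffusionComponents:
    def test_line_segment_dc1_monotone(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.zeros(50)])
        dcs = diffusion_components(pts, k=5, n_components=2)
        rho = spearmanr(dcs[:, 0], pts[:, 0]).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_sign_convention_nonnegative_corr_with_first_feature(self):
        pts = np.column_stack([np.linspace(0, 1, 40), np.zeros(40)])
        dcs = diffusion_components(pts, k=4, n_components=1)
        assert np.corrcoef(dcs[:, 0], pts[:, 0])[0, 1] >= 0

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            diffusion_components(np.random.default_rng(0).normal(size=(10, 3)), k=10)
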