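"""Essential-dynamics PCA: independent decomposition routes and invariants."""

import numpy as np
import pytest

from mntrdyn.errors import InsufficientDataError, ShapeError, StructuralMismatchError
from mntrdyn.pca import fit_pca, merge_and_superpose, project, residue_loadings
from mntrdyn.structio import Selection, Trajectory
from mntrdyn.synthdata import generate_ensemble, preset_params


@pytest.fixture(scope="module")
def random_coords():
    rng = np.random.default_rng(7)
    return rng.normal(size=(60, 15)) * rng.uniform(0.5, 3.0, size=15)


class TestFitPca:
    def test_single_direction_data(self, rng):
        direction = rng.normal(size=9)
        direction /= np.linalg.norm(direction)
        coords = np.outer(rng.normal(size=40), direction)
        res = fit_pca(coords)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(res.variance_fractions[1:], 0.0, atol=1e-10)

    def test_isotropic_jitter_equal_eigenvalues(self):
        """Isotropic Gaussian coordinates: all eigenvalues equal in
        expectation (closed form: sigma^2), checked at n=10^4."""
        rng = np.random.default_rng(42)
        sigma = 0.7
        n, p = 10_000, 12
        coords = rng.normal(0.0, sigma, size=(n, p))
        res = fit_pca(coords)
        # sample eigenvalues of white noise spread over ~(1 ± sqrt(p/n))^2
        edge = sigma**2 * ((1 + np.sqrt(p / n)) ** 2 - 1) * 1.5
        assert np.all(np.abs(res.eigenvalues - sigma**2) < edge)

    def test_matches_svd_route(self, random_coords):
        """Eigenpairs agree with an independent SVD of the centered data."""
        res = fit_pca(random_coords)
        centered = random_coords - random_coords.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        eig_svd = s**2 / (random_coords.shape[0] - 1)
        k = len(eig_svd)
        assert np.allclose(res.eigenvalues[:k], eig_svd, atol=1e-8)
        for i in range(k):
            if eig_svd[i] > 1e-10:
                dot = abs(np.dot(res.eigenvectors[:, i], vt[i]))
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_variance_conservation_and_orthonormality(self, random_coords):
        res = fit_pca(random_coords)
        cov_trace = np.trace(np.cov(random_coords.T, ddof=1))
        assert res.eigenvalues.sum() == pytest.approx(cov_trace, abs=1e-8)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)
        gram = res.eigenvectors.T @ res.eigenvectors
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_frame_order_invariance(self, random_coords, rng):
        res1 = fit_pca(random_coords)
        res2 = fit_pca(random_coords[rng.permutation(len(random_coords))])
        assert np.allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)

    def test_static_input_flagged(self):
        coords = np.ones((5, 6))
        res = fit_pca(coords)
        assert res.zero_variance
        assert np.allclose(res.variance_fractions, 0.0)

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            fit_pca(np.ones((1, 6)))


class TestProject:
    def test_mean_projects_to_zero(self, random_coords):
        res = fit_pca(random_coords)
        assert project(res.mean_coords, res, 0)[0] == pytest.approx(0.0, abs=1e-10)

    def test_full_basis_reconstructs_data(self, random_coords):
        res = fit_pca(random_coords)
        centered = random_coords - res.mean_coords
        proj = np.stack(
            [project(random_coords, res, k) for k in range(res.component_count)], axis=1
        )
        assert np.allclose(proj @ res.eigenvectors.T, centered, atol=1e-8)

    def test_component_out_of_range(self, random_coords):
        res = fit_pca(random_coords)
        with pytest.raises(ShapeError):
            project(random_coords, res, res.component_count)


class TestLoadings:
    def test_equals_correlation_oracle(self, random_coords):
        """Per-coordinate loadings equal corr(coordinate, projection)."""
        res = fit_pca(random_coords)
        p1 = project(random_coords, res, 0)
        lp = residue_loadings(res, random_coords, 0)
        for j in range(random_coords.shape[1]):
            r = np.corrcoef(random_coords[:, j], p1)[0, 1]
            assert lp.per_coordinate[j] == pytest.approx(r, abs=1e-8)

    def test_single_moving_residue_carries_all_loading(self, rng):
        coords = np.zeros((50, 12)) + rng.normal(size=12)
        coords[:, 3] += rng.normal(size=50)  # atom 1, x coordinate
        res = fit_pca(coords)
        lp = residue_loadings(res, coords, 0)
        assert lp.values[1] == pytest.approx(1.0, abs=1e-8)
        others = np.delete(lp.values, 1)
        assert np.allclose(others, 0.0, atol=1e-8)
        assert lp.zero_variance_coords.sum() == 11

    def test_perfectly_correlated_coordinate_has_unit_loading(self, rng):
        t = rng.normal(size=80)
        coords = np.outer(t, np.array([1.0, -2.0, 0.5, 3.0, 0.0, 1.0]))
        coords[:, 4] = rng.normal(size=80) * 1e-3  # a tiny independent wiggle
        res = fit_pca(coords)
        lp = residue_loadings(res, coords, 0)
        for j in (0, 1, 2, 3, 5):
            assert abs(lp.per_coordinate[j]) == pytest.approx(1.0, abs=1e-6)


class TestMergeAndSuperpose:
    def test_static_trajectory_rows_equal_mean(self, rng):
        frame = rng.normal(size=(8, 3)) * 4
        traj = _toy_traj(np.repeat(frame[None], 6, axis=0))
        flat = merge_and_superpose([traj])
        assert np.allclose(flat, flat.mean(axis=0), atol=1e-9)

    def test_duplication_leaves_covariance_unchanged(self, apo_small):
        sel = Selection.ca()
        one = merge_and_superpose([apo_small], sel)
        two = merge_and_superpose([apo_small, apo_small], sel)
        assert two.shape[0] == 2 * one.shape[0]
        c1 = np.cov(one.T, ddof=0)
        c2 = np.cov(two.T, ddof=0)
        assert np.allclose(c1, c2, atol=1e-8)

    def test_matches_reference_fit_to_mean_loop(self, rng):
        """Independent two-pass reference implementation of the mean fit."""
        from mntrdyn.geometry import superpose

        coords = rng.normal(size=(12, 6, 3)) * 0.3 + rng.normal(size=(6, 3)) * 8
        flat = merge_and_superpose([_toy_traj(coords)])

        work = coords.copy()
        ref = work[0] - work[0].mean(axis=0)
        for _ in range(300):
            work = np.stack([superpose(f, ref) for f in work])
            mean = work.mean(axis=0)
            if np.sqrt(np.mean(np.sum((mean - ref) ** 2, -1))) < 1e-6:
                ref = mean
                break
            ref = mean
        assert np.allclose(flat, work.reshape(12, -1), atol=1e-5)

    def test_mismatched_tables_raise(self, apo_small, rng):
        other = _toy_traj(rng.normal(size=(4, 5, 3)))
        with pytest.raises(StructuralMismatchError):
            merge_and_superpose([apo_small, other])

    def test_window_filters_frames(self, apo_small):
        flat = merge_and_superpose([apo_small], Selection.ca(), window=(5000, 10000))
        assert flat.shape[0] == 50


def test_pc1_separates_apo_from_mn_states(apo_small, mn_small):
    """Merged two-state PCA: PC1 projections split the labels by > 2 pooled SDs,
    and the strongest residue loadings sit in the mobile DNA-binding block."""
    sel = Selection.ca(3, 7)
    coords, origin, table = merge_and_superpose(
        [apo_small, mn_small], sel, return_origin=True)
    res = fit_pca(coords)
    p1 = project(coords, res, 0)
    a, m = p1[origin == 0], p1[origin == 1]
    pooled = np.sqrt((a.var(ddof=1) + m.var(ddof=1)) / 2)
    assert abs(a.mean() - m.mean()) > 2 * pooled

    lp = residue_loadings(res, coords, 0, table)
    top10 = np.argsort(lp.values)[::-1][:10]
    in_mobile = (lp.res_nums[top10] <= 74).mean()  # DBD block + hinge arm
    assert lp.res_nums[np.argmax(lp.values)] <= 74
    assert in_mobile >= 0.7


def _toy_traj(coords):
    from mntrdyn.structio import AtomTable

    n = coords.shape[1]
    table = AtomTable(
        np.repeat("A", n), np.arange(1, n + 1), np.repeat("GLY", n), np.repeat("CA", n)
    )
    return Trajectory(table, coords, 100.0)
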