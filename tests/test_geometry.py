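"""Geometric kernels against closed forms and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mntrdyn.errors import DegenerateGeometryError, InsufficientDataError, ShapeError
from mntrdyn.geometry import (
    RigidTransform,
    angle,
    dihedral,
    kabsch,
    iterative_mean_superpose,
    radius_of_gyration,
    rmsf,
    superpose,
)

from conftest import random_rigid_transform


def dihedral_oracle(p1, p2, p3, p4):
    """Independent textbook torsion: project onto the plane normal to the
    central bond and take the signed angle (praxeolitic formula)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    b2 = p4 - p3
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


finite_coord = st.floats(-50, 50, allow_nan=False, allow_infinity=False)
point = st.tuples(finite_coord, finite_coord, finite_coord).map(np.array)


class TestAngle:
    @pytest.mark.parametrize(
        "p1,p2,p3,expected",
        [
            ((0, 0, 0), (1, 0, 0), (2, 0, 0), 180.0),
            ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (0.5, np.sqrt(3) / 2, 0), (0, 0, 0), 60.0),
        ],
    )
    def test_closed_forms(self, p1, p2, p3, expected):
        assert angle(p1, p2, p3) == pytest.approx(expected, abs=1e-9)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_vectorised_matches_scalar(self, rng):
        pts = rng.normal(size=(10, 3, 3)) * 5
        vec = angle(pts[:, 0], pts[:, 1], pts[:, 2])
        ref = [angle(*p) for p in pts]
        assert np.allclose(vec, ref)


class TestDihedral:
    def test_cis_trans(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0, abs=1e-9)
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_against_independent_oracle(self, rng):
        for _ in range(50):
            p = rng.normal(size=(4, 3)) * 8
            assert dihedral(*p) == pytest.approx(dihedral_oracle(*p), abs=1e-9)

    def test_reversal_invariance_and_mirror_antisymmetry(self, rng):
        """Reading the four atoms backwards leaves the IUPAC torsion
        unchanged; a mirror reflection flips its sign."""
        for _ in range(20):
            p = rng.normal(size=(4, 3)) * 5
            fwd = dihedral(*p)
            assert dihedral(p[3], p[2], p[1], p[0]) == pytest.approx(fwd, abs=1e-9)
            mirrored = p * np.array([1.0, 1.0, -1.0])
            assert dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-9) or (
                abs(fwd) == pytest.approx(180.0, abs=1e-7)
            )

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @given(data=st.data())
    def test_rigid_motion_invariance(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        p = rng.normal(size=(4, 3)) * 6
        # reject degenerate draws
        if np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[1])) < 1e-3:
            return
        if np.linalg.norm(np.cross(p[2] - p[1], p[3] - p[2])) < 1e-3:
            return
        R, t = random_rigid_transform(rng)
        q = p @ R.T + t
        assert dihedral(*q) == pytest.approx(dihedral(*p), abs=1e-6)
        assert angle(*q[:3]) == pytest.approx(angle(*p[:3]), abs=1e-6)


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        x = rng.normal(size=(8, 3))
        tf, val = kabsch(x, x)
        assert val == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-8)

    def test_pure_translation(self, rng):
        x = rng.normal(size=(6, 3))
        tf, val = kabsch(x + np.array([5.0, 5.0, 5.0]), x)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_displaced_point_matches_numeric_oracle(self):
        """4-point set with one point moved 1 Å: compare with a rotation-grid
        search refined by numerical optimisation (independent route)."""
        ref = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        mob = ref.copy()
        mob[3, 2] += 1.0
        _, val = kabsch(mob, ref)

        def cost(v):
            R = Rotation.from_rotvec(v).as_matrix()
            a = (mob - mob.mean(0)) @ R.T + ref.mean(0)
            return np.sqrt(np.mean(np.sum((a - ref) ** 2, axis=1)))

        grid = Rotation.random(300, random_state=0).as_rotvec()
        best = min((minimize(cost, g, method="Nelder-Mead").fun for g in grid[:40]),
                   default=np.inf)
        best = min(best, min(cost(g) for g in grid))
        assert val == pytest.approx(best, abs=1e-4)
        assert val <= best + 1e-9

    def test_dominates_sampled_rotations(self, rng):
        """Oracle dominance: no sampled rotation beats the closed form."""
        for _ in range(5):
            mob = rng.normal(size=(12, 3)) * 4
            ref = rng.normal(size=(12, 3)) * 4
            _, val = kabsch(mob, ref)
            Rg = Rotation.random(500, random_state=1).as_matrix()
            mc = mob - mob.mean(0)
            rc = ref - ref.mean(0)
            sampled = np.sqrt(
                np.mean(np.sum((np.einsum("rij,nj->rni", Rg, mc) - rc) ** 2, -1), -1)
            )
            assert val <= sampled.min() + 1e-9

    def test_symmetry_and_rigid_invariance(self, rng):
        a = rng.normal(size=(10, 3)) * 3
        b = rng.normal(size=(10, 3)) * 3
        _, v1 = kabsch(a, b)
        _, v2 = kabsch(b, a)
        assert v1 == pytest.approx(v2, abs=1e-8)
        R, t = random_rigid_transform(rng)
        _, v3 = kabsch(a @ R.T + t, b)
        assert v3 == pytest.approx(v1, abs=1e-8)

    def test_reflection_excluded(self):
        """A mirror image must not be matched by an improper rotation."""
        x = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2], [1, 1, 1]], float)
        mirrored = x * np.array([1, 1, -1])
        tf, val = kabsch(mirrored, x)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)
        assert val > 0.1

    def test_errors(self, rng):
        with pytest.raises(ShapeError):
            kabsch(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
        with pytest.raises(DegenerateGeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            kabsch(line, line)


class TestRmsfRg:
    def test_static_trajectory_zero(self, rng):
        frame = rng.normal(size=(20, 3))
        coords = np.repeat(frame[None], 5, axis=0)
        assert np.allclose(rmsf(coords), 0.0, atol=1e-10)

    def test_alternating_atom_closed_form(self):
        """Two atoms breathing radially in antiphase: the motion has no net
        translation or rotation, so superposition is a no-op and the RMSF of
        each moving atom is exactly the half-amplitude d."""
        base = np.array([
            [10, 0, 0], [-10, 0, 0],
            [0, 10, 0], [0, -10, 0], [0, 0, 10], [0, 0, -10],
        ], float)
        coords = np.repeat(base[None], 4, axis=0)
        d = 0.3
        coords[::2, 0, 0] += d
        coords[1::2, 0, 0] -= d
        coords[::2, 1, 0] -= d
        coords[1::2, 1, 0] += d
        out = rmsf(coords)
        assert out[0] == pytest.approx(d, abs=1e-9)
        assert out[1] == pytest.approx(d, abs=1e-9)
        assert np.allclose(out[2:], 0.0, atol=1e-9)

    def test_matches_two_pass_variance_oracle(self, rng):
        coords = rng.normal(size=(30, 6, 3)) * 0.2 + rng.normal(size=(6, 3)) * 10
        fitted, mean = iterative_mean_superpose(coords)
        oracle = np.sqrt(((fitted - mean) ** 2).sum(-1).mean(0))
        assert np.allclose(rmsf(coords), oracle, atol=1e-10)

    def test_single_frame_raises(self, rng):
        with pytest.raises(InsufficientDataError):
            rmsf(rng.normal(size=(1, 5, 3)))

    @pytest.mark.parametrize(
        "coords,expected",
        [
            (np.zeros((1, 3)), 0.0),
            (np.array([[0, 0, 0], [4, 0, 0]]), 2.0),
            (np.array([[sx, sy, sz] for sx in (0, 2) for sy in (0, 2) for sz in (0, 2)],
                      dtype=float), np.sqrt(3)),
        ],
    )
    def test_radius_of_gyration(self, coords, expected):
        assert radius_of_gyration(coords) == pytest.approx(expected, abs=1e-12)


def test_rigid_transform_validation():
    with pytest.raises(DegenerateGeometryError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    tf = RigidTransform.identity()
    x = np.arange(12.0).reshape(4, 3)
    assert np.allclose(tf.apply(x), x)


def test_superpose_recovers_rigid_copy(rng):
    x = rng.normal(size=(9, 3)) * 5
    R, t = random_rigid_transform(rng)
    assert np.allclose(superpose(x @ R.T + t, x), x, atol=1e-8)
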