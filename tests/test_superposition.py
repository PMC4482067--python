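"""Rigid-body superposition: optimality, invariance, outlier rejection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from rnapivot.correspondence import pair_atoms, pair_residues
from rnapivot.superposition import (
    DegenerateInputError,
    kabsch,
    refine_superposition,
    rmsd,
    transform,
)
from rnapivot.synthetic import make_aform_duplex


def _random_points(n, seed):
    return np.random.default_rng(seed).normal(0.0, 10.0, (n, 3))


def _random_rigid(rng):
    rot = Rotation.random(rng=rng).as_matrix()
    return rot, rng.normal(0.0, 20.0, 3)


def test_identical_coordinates_give_identity():
    pts = _random_points(20, 0)
    sr = kabsch(pts, pts)
    np.testing.assert_allclose(sr.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(sr.translation, 0.0, atol=1e-12)
    assert sr.rmsd_all < 1e-12


def test_exact_rigid_motion_is_inverted():
    pts = _random_points(25, 1)
    rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = pts @ rot.T + np.array([1.0, 2.0, 3.0])
    sr = kabsch(pts, moved)
    assert sr.rmsd_all < 1e-10
    np.testing.assert_allclose(sr.apply(moved), pts, atol=1e-9)


def test_rotation_is_always_proper():
    # near-planar points exercise the reflection branch
    rng = np.random.default_rng(2)
    pts = rng.normal(0.0, 5.0, (10, 3))
    pts[:, 2] *= 1e-6
    mirrored = pts * np.array([1.0, 1.0, -1.0])
    sr = kabsch(pts, mirrored)
    assert abs(np.linalg.det(sr.rotation) - 1.0) < 1e-8
    assert np.abs(sr.rotation @ sr.rotation.T - np.eye(3)).max() < 1e-8


def test_optimality_against_random_rigid_transforms():
    """The fitted RMSD never exceeds the RMSD under any random rigid motion
    of the mobile set (brute-force check of least-squares optimality)."""
    rng = np.random.default_rng(42)
    pts = _random_points(10, 3)
    noisy = pts + rng.normal(0.0, 0.5, pts.shape)
    best = kabsch(pts, noisy).rmsd_all
    rots = Rotation.random(1000, rng=rng).as_matrix()
    shifts = rng.normal(0.0, 5.0, (1000, 3))
    moved = np.einsum("kij,nj->kni", rots, noisy) + shifts[:, None, :]
    alt = np.sqrt(np.mean(np.sum((moved - pts) ** 2, axis=2), axis=1))
    assert best <= alt.min() + 1e-9


def test_agreement_with_scipy_reference():
    rng = np.random.default_rng(7)
    a = _random_points(40, 8)
    b = a + rng.normal(0.0, 1.0, a.shape)
    sr = kabsch(a, b)
    ref_rot, ref_rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
    np.testing.assert_allclose(sr.rotation, ref_rot.as_matrix(), atol=1e-8)
    np.testing.assert_allclose(sr.rmsd_all, ref_rssd / np.sqrt(len(a)), atol=1e-8)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_rmsd_invariant_under_rigid_premotion(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 8.0, (15, 3))
    b = a + rng.normal(0.0, 0.7, a.shape)
    base = kabsch(a, b).rmsd_all
    rot, shift = _random_rigid(rng)
    assert abs(kabsch(a, b @ rot.T + shift).rmsd_all - base) < 1e-6
    assert abs(kabsch(a @ rot.T + shift, b).rmsd_all - base) < 1e-6


def test_weighted_fit_prefers_heavy_points():
    a = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [5.0, 5.0, 5.0]])
    b = a.copy()
    b[3] += [0.0, 0.0, 4.0]
    w = np.array([1.0, 1.0, 1.0, 1e-9])
    sr = kabsch(a, b, weights=w)
    # the down-weighted outlier no longer drags the frame
    np.testing.assert_allclose(sr.apply(b)[:3], a[:3], atol=1e-6)


def test_degenerate_inputs_rejected():
    with pytest.raises(DegenerateInputError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


@pytest.mark.parametrize("case,expected", [
    ("identical", 0.0),
    ("two_at_d", 2.5),
    ("one_two_two", np.sqrt(3.0)),
])
def test_rmsd_closed_forms(case, expected):
    if case == "identical":
        a = b = _random_points(6, 0)
    elif case == "two_at_d":
        a = np.zeros((2, 3))
        b = np.array([[2.5, 0, 0], [0, 2.5, 0]])
    else:  # three points at distances 1, 2, 2 -> sqrt((1+4+4)/3) = sqrt(3)
        a = np.zeros((3, 3))
        b = np.array([[1.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0]])
    assert rmsd(a, b) == pytest.approx(expected, abs=1e-12)


def test_rmsd_is_symmetric():
    rng = np.random.default_rng(11)
    a = rng.normal(size=(30, 3))
    b = rng.normal(size=(30, 3))
    assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-14)


class TestRefinement:
    def _pairing(self, model_a, model_b):
        rp = pair_residues(model_a, model_b, "by_number")
        return pair_atoms(rp, model_a, model_b)

    def test_noiseless_copy_terminates_without_rejection(self, duplex10):
        ap = self._pairing(duplex10, duplex10)
        sr = refine_superposition(ap, duplex10, duplex10)
        assert sr.n_rejected == 0
        assert sr.rmsd_kept < 1e-10

    def test_single_displaced_atom_is_rejected(self, duplex10):
        """A rigid copy with one atom thrown 20 Å off: that single pair is
        discarded and the retained fit is numerically exact."""
        b = duplex10.copy()
        b.chains["A"][3].atoms[0].position = \
            b.chains["A"][3].atoms[0].position + np.array([20.0, 0.0, 0.0])
        ap = self._pairing(duplex10, b)
        sr = refine_superposition(ap, duplex10, b)
        assert sr.n_rejected == 1
        assert sr.rmsd_kept < 1e-6
        assert sr.rmsd_all > 0.1          # the outlier still counts here

    def test_zero_cycles_equals_plain_kabsch(self, duplex10):
        b = duplex10.copy()
        rng = np.random.default_rng(3)
        for res in b.chains["A"]:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0.0, 0.4, 3)
        ap = self._pairing(duplex10, b)
        sr0 = refine_superposition(ap, duplex10, b, max_cycles=0)
        ca, cb = ap.coordinates(duplex10, b)
        plain = kabsch(ca, cb)
        assert sr0.cycles_run == 0
        assert sr0.rmsd_all == pytest.approx(plain.rmsd_all, abs=1e-12)

    def test_rmsd_kept_monotone_over_cycles(self, duplex10):
        b = duplex10.copy()
        rng = np.random.default_rng(5)
        for res in b.chains["A"]:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(0.0, 0.8, 3)
        ap = self._pairing(duplex10, b)
        history = [refine_superposition(ap, duplex10, b, max_cycles=k).rmsd_kept
                   for k in range(5)]
        assert all(later <= earlier + 1e-12
                   for earlier, later in zip(history, history[1:]))
        assert all(refine_superposition(ap, duplex10, b, max_cycles=k).rmsd_kept
                   <= refine_superposition(ap, duplex10, b, max_cycles=k).rmsd_all
                   for k in (2, 4))


def test_transform_moves_all_coordinates(duplex10):
    pts = _random_points(30, 9)
    rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
    sr = kabsch(pts @ rot.T + 5.0, pts)
    moved = transform(duplex10, sr)
    expected = duplex10.all_coords() @ sr.rotation.T + sr.translation
    np.testing.assert_allclose(moved.all_coords(), expected, atol=1e-12)
    assert moved.n_atoms() == duplex10.n_atoms()
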