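"""Least-squares rigid-body superposition with iterative outlier rejection.

The core is the classical SVD solution of the orthogonal Procrustes problem
(Kabsch): given paired point sets it returns the proper rotation and
translation minimising the (weighted) sum of squared distances of the mobile
set onto the fixed set.  On top of it, :func:`refine_superposition` mimics
the behaviour of interactive fitting tools that discard a fraction of badly
fitting atom pairs over a few cycles to produce a best fit of the consistent
core, while still reporting the RMSD over all originally paired atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correspondence import AtomPairing
from .structure_io import StructureModel

__all__ = ["SuperpositionResult", "kabsch", "refine_superposition", "transform", "rmsd"]


class DegenerateInputError(ValueError):
    """Fewer than 3 point pairs, or degenerate geometry."""


@dataclass
class SuperpositionResult:
    """Rotation/translation plus RMSD bookkeeping for one alignment.

    The transform maps mobile coordinates x onto the fixed frame as
    ``R @ x + t``.  ``rmsd_all`` is measured over every input pair after the
    final transform; ``rmsd_kept`` over the pairs retained by outlier
    rejection (equal to ``rmsd_all`` when nothing was rejected).
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_all: float
    rmsd_kept: float
    n_input: int
    n_rejected: int = 0
    cycles_run: int = 0
    converged: bool = True
    kept_mask: np.ndarray | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square of pairwise Euclidean distances, Å."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape != b.shape or len(a) == 0:
        raise ValueError("coordinate arrays must be equal-length and non-empty")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal rigid superposition of ``coords_b`` onto ``coords_a``.

    Minimises ``sum_i w_i |a_i - (R b_i + t)|^2`` over proper rotations R.
    The reflection branch of the SVD solution is corrected by flipping the
    sign of the smallest singular direction, so the result is always a
    rotation (det = +1).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected matching (N, 3) coordinate arrays")
    n = len(a)
    if n < 3:
        raise DegenerateInputError(f"need at least 3 atom pairs, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()

    cen_a = w @ a
    cen_b = w @ b
    a0 = a - cen_a
    b0 = b - cen_b
    h = (a0 * w[:, None]).T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rot = u @ flip @ vt
    trans = cen_a - rot @ cen_b
    fitted = b @ rot.T + trans
    r = rmsd(a, fitted)
    return SuperpositionResult(
        rotation=rot, translation=trans, rmsd_all=r, rmsd_kept=r,
        n_input=n, n_rejected=0, cycles_run=0,
        kept_mask=np.ones(n, dtype=bool),
    )


def refine_superposition(
    ap: AtomPairing,
    a: StructureModel,
    b: StructureModel,
    max_cycles: int = 5,
    reject_sigma: float = 2.0,
    convergence_rmsd: float = 1e-8,
) -> SuperpositionResult:
    """Superpose with iterative rejection of badly fitting atom pairs.

    After each fit, pairs whose post-fit distance exceeds
    ``reject_sigma x rmsd_kept`` are dropped and the remainder refit, for at
    most ``max_cycles`` cycles or until no pair is rejected.  Rejection stops
    early once ``rmsd_kept`` falls below ``convergence_rmsd`` (the threshold
    would otherwise degenerate on exact rigid copies).  If a cycle would
    leave fewer than 3 pairs the last valid fit is returned with
    ``converged=False``.  ``rmsd_all`` is always reported over the original
    pairing under the final transform.
    """
    ca, cb = ap.coordinates(a, b)
    n = len(ca)
    result = kabsch(ca, cb)
    kept = np.ones(n, dtype=bool)
    cycles = 0
    for _ in range(max_cycles):
        if result.rmsd_kept <= convergence_rmsd:
            break
        dist = np.linalg.norm(ca - result.apply(cb), axis=1)
        reject = kept & (dist > reject_sigma * result.rmsd_kept)
        if not reject.any():
            break
        new_kept = kept & ~reject
        if new_kept.sum() < 3:
            result.converged = False
            break
        kept = new_kept
        cycles += 1
        sub = kabsch(ca[kept], cb[kept])
        result = SuperpositionResult(
            rotation=sub.rotation,
            translation=sub.translation,
            rmsd_all=rmsd(ca, sub.apply(cb)),
            rmsd_kept=sub.rmsd_kept,
            n_input=n,
            n_rejected=int(n - kept.sum()),
            cycles_run=cycles,
            kept_mask=kept.copy(),
        )
    result.n_input = n
    result.cycles_run = cycles
    return result


def transform(model: StructureModel, sr: SuperpositionResult) -> StructureModel:
    """Return a copy of the model with all coordinates mapped by ``sr``."""
    out = model.copy()
    for res in out.residues():
        for atom in res.atoms:
            atom.position = sr.rotation @ atom.position + sr.translation
    return out
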