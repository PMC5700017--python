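"""Rigid-body superposition and the RMSD flavors used throughout.

All superposition goes through the SVD form of the Kabsch algorithm with a
determinant sign fix, so reflections are never returned.  Chain-level RMSD
comes in three selections: cRMSD over Cα atoms, bRMSD over backbone heavy
atoms (N, CA, C, O) and aRMSD over all heavy atoms shared by both chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .structure_io import BACKBONE_ATOMS, PeptideChain

#: Orthogonality tolerance for validated rotation matrices.
ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class Transform:
    """A proper rigid motion x ↦ R·x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("transform must be a 3x3 rotation and a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise GeometryError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation matrix is a reflection")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))


def _as_points(P, name: str) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError(f"{name} must be an N x 3 array")
    return P


def kabsch(P, Q) -> tuple[Transform, float]:
    """Optimal proper rigid motion taking point set P onto Q.

    Returns the minimizing :class:`Transform` and the residual RMSD in Å.
    Requires N ≥ 3 paired points and at least rank-2 (non-collinear) point
    sets; reflections are excluded by flipping the sign of the smallest
    singular axis when needed.
    """
    P = _as_points(P, "P")
    Q = _as_points(Q, "Q")
    if P.shape != Q.shape:
        raise GeometryError(f"point count mismatch: {P.shape[0]} vs {Q.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    scale = max(np.abs(P0).max(), np.abs(Q0).max(), 1.0)
    if (np.linalg.matrix_rank(P0, tol=1e-8 * scale) < 2
            or np.linalg.matrix_rank(Q0, tol=1e-8 * scale) < 2):
        raise GeometryError("degenerate (collinear) point set: rotation underdetermined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    # residual computed directly (the trace formula cancels badly near zero)
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return Transform(R, t), rmsd


def rmsd_no_fit(P, Q) -> float:
    """Plain RMSD between paired coordinates, without superposition."""
    P = _as_points(P, "P")
    Q = _as_points(Q, "Q")
    if P.shape != Q.shape:
        raise GeometryError(f"point count mismatch: {P.shape[0]} vs {Q.shape[0]}")
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


_SELECTION_MODES = ("ca", "backbone", "heavy")


def _selection_coords(model: PeptideChain, reference: PeptideChain,
                      mode: str) -> tuple[np.ndarray, np.ndarray]:
    pm, pr = [], []
    for rm, rr in zip(model.residues, reference.residues):
        if mode == "ca":
            names = ["CA"]
        elif mode == "backbone":
            names = list(BACKBONE_ATOMS)
        elif mode == "heavy":
            have = set(rr.atom_names)
            names = [n for n in rm.atom_names if n in have]
        else:
            raise GeometryError(f"unknown selection mode {mode!r}; use one of {_SELECTION_MODES}")
        for n in names:
            pm.append(rm.atom(n).coord)
            pr.append(rr.atom(n).coord)
    if not pm:
        raise GeometryError("empty atom selection")
    return np.array(pm), np.array(pr)


def ensemble_rmsd(model: PeptideChain, reference: PeptideChain, mode: str = "ca") -> float:
    """Superposed RMSD between a model and a reference of the same sequence.

    ``mode`` selects the atom set: ``"ca"`` (cRMSD), ``"backbone"`` (bRMSD,
    N/CA/C/O) or ``"heavy"`` (aRMSD over heavy atoms present in both, paired
    by name with no symmetry correction).
    """
    if model.sequence != reference.sequence:
        raise GeometryError(
            f"sequence mismatch: {model.sequence!r} vs {reference.sequence!r}")
    P, Q = _selection_coords(model, reference, mode)
    _, rmsd = kabsch(P, Q)
    return rmsd


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    n1 = np.linalg.norm(b1)
    if n1 == 0:
        raise GeometryError("dihedral undefined: zero-length central bond")
    b1u = b1 / n1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D bonded to C.

    D is placed at distance ``bond`` from C, with angle B-C-D ``angle_deg``
    and torsion A-B-C-D ``torsion_deg`` (degrees).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = bond * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(chi),
        np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    n_bc = np.linalg.norm(bc)
    if n_bc == 0:
        raise GeometryError("place_atom: coincident B and C")
    bc /= n_bc
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise GeometryError("place_atom: collinear A, B, C")
    n /= n_norm
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local
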