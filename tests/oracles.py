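"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: superposition
goes through the quaternion (Horn) eigenvalue method instead of SVD, the
clustering oracle recomputes every distance from scratch, and the chain
audit uses plain O(n^2) loops instead of a KD-tree.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def _key_matrix(P0: np.ndarray, Q0: np.ndarray) -> np.ndarray:
    S = P0.T @ Q0
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    return np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD over proper rotations via the quaternion eigenvalue method."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    lam = np.linalg.eigvalsh(_key_matrix(P0, Q0))[-1]
    ssd = (P0 * P0).sum() + (Q0 * Q0).sum() - 2.0 * lam
    return float(np.sqrt(max(ssd, 0.0) / len(P)))


def quaternion_superpose(P: np.ndarray, Q: np.ndarray):
    """(R, t) minimizing |R·P + t − Q| from the dominant quaternion."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    w, v = np.linalg.eigh(_key_matrix(P - pc, Q - qc))
    q0, q1, q2, q3 = v[:, -1]
    R = np.array([
        [q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
        [2 * (q1 * q2 + q0 * q3), q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3, 2 * (q2 * q3 - q0 * q1)],
        [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3],
    ])
    return R, qc - R @ pc


def brute_force_leader_clusters(records, threshold: float):
    """Reference leader clustering over ConformerRecord-like objects.

    Visits conformers sorted by (resolution, source_id, index); assigns each
    to the first representative within ``threshold`` (RMSD over rmsd_coords
    after quaternion superposition of align_coords), else founds a cluster.
    Returns a list of (representative_index, sorted member indices).
    """
    def reskey(r):
        return 0.0 if r.resolution is None else r.resolution

    order = sorted(range(len(records)),
                   key=lambda i: (reskey(records[i]), records[i].source_id, i))
    clusters: list[list[int]] = []
    reps: list[int] = []
    for idx in order:
        rec = records[idx]
        for ci, rep_idx in enumerate(reps):
            rep = records[rep_idx]
            R, t = quaternion_superpose(rec.align_coords, rep.align_coords)
            moved = rec.rmsd_coords @ R.T + t
            d = np.sqrt(np.mean(np.sum((moved - rep.rmsd_coords) ** 2, axis=1)))
            if d < threshold:
                clusters[ci].append(idx)
                break
        else:
            reps.append(idx)
            clusters.append([idx])
    return [(reps[i], sorted(clusters[i])) for i in range(len(reps))]


def exact_probability_sum(entries) -> Fraction:
    """Sum of cluster_size/total as exact rationals."""
    return sum((Fraction(e.cluster_size, e.total) for e in entries), Fraction(0))


def audit_chain(chain, clash_distance: float = 2.0, bond_range=(1.2, 1.5)):
    """Geometric validity audit; returns a list of human-readable problems."""
    problems = []
    n = len(chain)
    for i in range(n - 1):
        c = chain.residues[i].atom("C").coord
        nn = chain.residues[i + 1].atom("N").coord
        d = float(np.linalg.norm(c - nn))
        if not bond_range[0] <= d <= bond_range[1]:
            problems.append(f"peptide bond {i}-{i + 1}: {d:.3f} Å")
    atoms = [(ri, a.name, a.coord) for ri, res in enumerate(chain.residues)
             for a in res.atoms]
    for x in range(len(atoms)):
        ri, ni, ci = atoms[x]
        for y in range(x + 1, len(atoms)):
            rj, nj, cj = atoms[y]
            if abs(ri - rj) < 2:
                continue
            d = float(np.linalg.norm(ci - cj))
            if d < clash_distance:
                problems.append(f"clash {ri}:{ni} vs {rj}:{nj} at {d:.3f} Å")
    return problems
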