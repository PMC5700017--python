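"""Synthetic peptide structures built from internal coordinates.

This module stands in for an experimental training/test set: it constructs
geometrically exact peptides (NeRF internal→Cartesian chain extension) with
standard bond lengths and angles, ideal α-helices, Ramachandran-sampled
coils, and mixed "training sets" carrying pseudo-resolutions, so that
library construction, assembly and evaluation are all exercisable offline.

Side chains are placed from a small built-in ideal-geometry table with χ
angles at common rotamer values — chemically plausible, not Dunbrack-grade.
The proline ring is approximated (it does not close exactly) and proline φ
is pinned to −65° by the coil sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BuildError, PepforgeError
from .geometry import place_atom
from .structure_io import Atom, ONE_TO_THREE, PeptideChain, Residue

# Standard peptide backbone geometry (Engh–Huber-like values), Å and degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# CB placement as a NeRF improper off the backbone: torsion N-C-CA-CB for
# L-amino acids (measured on an energy-minimized L-alanine model).
_CB = ("CB", "C", ("N", "C", "CA"), 1.530, 110.5, 121.6, 0)

# Side-chain rows: (name, element, (a, b, c) parents, bond, angle,
# torsion offset, chi index).  torsion = offset for chi index 0, else
# chi[index-1] + offset so user-supplied χ angles propagate.
_SIDE_CHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, 0.0, 1)],
    "CYS": [_CB, ("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, 0.0, 1)],
    "THR": [_CB,
            ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.5, 0.0, 1),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, -122.0, 1)],
    "VAL": [_CB,
            ("CG1", "C", ("N", "CA", "CB"), 1.521, 110.5, 0.0, 1),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, -122.0, 1)],
    "LEU": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, 0.0, 1),
            ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, 0.0, 2),
            ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, 122.0, 2)],
    "ILE": [_CB,
            ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, 0.0, 1),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, -122.0, 1),
            ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, 0.0, 2)],
    "PRO": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, 0.0, 1),
            ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, 0.0, 2)],
    "MET": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 0.0, 1),
            ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, 0.0, 2),
            ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, 0.0, 3)],
    "ASP": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 0.0, 1),
            ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, 0.0, 2),
            ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, 180.0, 2)],
    "ASN": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 0.0, 1),
            ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, 0.0, 2),
            ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, 180.0, 2)],
    "GLU": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 0.0, 1),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 0.0, 2),
            ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, 0.0, 3),
            ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, 180.0, 3)],
    "GLN": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 0.0, 1),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 0.0, 2),
            ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, 0.0, 3),
            ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, 180.0, 3)],
    "LYS": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 0.0, 1),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 0.0, 2),
            ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, 0.0, 3),
            ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, 0.0, 4)],
    "ARG": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 0.0, 1),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 0.0, 2),
            ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, 0.0, 3),
            ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, 0.0, 4),
            ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.3, 0.0, 0),
            ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.3, 180.0, 0)],
    "HIS": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, 0.0, 1),
            ("ND1", "N", ("CA", "CB", "CG"), 1.371, 122.7, 0.0, 2),
            ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.2, 180.0, 2),
            ("CE1", "C", ("CB", "CG", "ND1"), 1.319, 109.3, 180.0, 0),
            ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0, 0)],
    "PHE": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, 0.0, 1),
            ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, 0.0, 2),
            ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, 180.0, 2),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0, 0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0, 0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 120.0, 0.0, 0)],
    "TYR": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.512, 113.9, 0.0, 1),
            ("CD1", "C", ("CA", "CB", "CG"), 1.389, 120.8, 0.0, 2),
            ("CD2", "C", ("CA", "CB", "CG"), 1.389, 120.8, 180.0, 2),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.1, 180.0, 0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.1, 180.0, 0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 119.5, 0.0, 0),
            ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0, 0)],
    "TRP": [_CB,
            ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, 0.0, 1),
            ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, 0.0, 2),
            ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, 180.0, 2),
            ("NE1", "N", ("CB", "CG", "CD1"), 1.375, 110.2, 180.0, 0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0, 0),
            ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0, 0),
            ("CZ2", "C", ("CG", "CD2", "CE2"), 1.398, 122.4, 180.0, 0),
            ("CZ3", "C", ("CG", "CD2", "CE3"), 1.392, 118.6, 180.0, 0),
            ("CH2", "C", ("CD2", "CE3", "CZ3"), 1.372, 121.1, 0.0, 0)],
}

#: Default χ angles (common rotamers) per residue type, degrees.
DEFAULT_CHI: dict[str, tuple[float, ...]] = {
    "SER": (-65.0,), "CYS": (-65.0,), "THR": (-60.0,), "VAL": (175.0,),
    "LEU": (-65.0, 175.0), "ILE": (-60.0, 170.0), "PRO": (27.0, -34.0),
    "MET": (-65.0, 180.0, -75.0), "ASP": (-70.0, -20.0), "ASN": (-65.0, -20.0),
    "GLU": (-65.0, 180.0, -20.0), "GLN": (-65.0, 180.0, -20.0),
    "LYS": (-65.0, 180.0, 180.0, 180.0), "ARG": (-65.0, 180.0, 180.0, 180.0),
    "HIS": (-65.0, -75.0), "PHE": (-65.0, 90.0), "TYR": (-65.0, 90.0),
    "TRP": (-65.0, 90.0),
}


@dataclass
class DihedralSpec:
    """Per-residue backbone dihedrals (degrees) with optional χ overrides."""

    phi: list[float]
    psi: list[float]
    omega: list[float] | None = None  # defaults to all-trans (180°)
    chi: list[tuple[float, ...] | None] | None = None

    def __post_init__(self) -> None:
        n = len(self.phi)
        if len(self.psi) != n:
            raise ValueError("phi and psi must have equal length")
        if self.omega is None:
            self.omega = [180.0] * n
        if len(self.omega) != n:
            raise ValueError("omega length mismatch")
        if self.chi is not None and len(self.chi) != n:
            raise ValueError("chi length mismatch")

    def __len__(self) -> int:
        return len(self.phi)


@dataclass
class RamachandranBasins:
    """Gaussian (φ, ψ) basins used by the coil sampler.

    Defaults cover the α (−57, −47, σ=10°), β (−120, 130, σ=15°) and
    polyproline-II (−75, 145, σ=10°) regions with weights 0.30/0.40/0.30.
    """

    names: tuple[str, ...] = ("alpha", "beta", "ppii")
    means: tuple[tuple[float, float], ...] = ((-57.0, -47.0), (-120.0, 130.0), (-75.0, 145.0))
    sigmas: tuple[float, ...] = (10.0, 15.0, 10.0)
    weights: tuple[float, ...] = (0.30, 0.40, 0.30)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("basin weights must sum to 1")


def _build_side_chain(aa3: str, backbone: dict[str, np.ndarray],
                      chi: tuple[float, ...] | None) -> list[Atom]:
    chi = chi if chi is not None else DEFAULT_CHI.get(aa3, ())
    placed = dict(backbone)
    atoms = []
    for name, elem, (a, b, c), bond, angle, offset, chik in _SIDE_CHAINS[aa3]:
        if chik == 0:
            torsion = offset
        else:
            if chik > len(chi):
                raise PepforgeError(f"{aa3}: missing chi{chik} angle")
            torsion = chi[chik - 1] + offset
        pos = place_atom(placed[a], placed[b], placed[c], bond, angle, torsion)
        placed[name] = pos
        atoms.append(Atom(name, elem, pos))
    return atoms


def chain_from_dihedrals(sequence: str, spec: DihedralSpec, chain_id: str = "A",
                         resolution: float | None = None,
                         source_id: str = "fixture") -> PeptideChain:
    """Build a complete heavy-atom peptide with the requested φ/ψ/ω.

    φ of the first residue and ψ-dependence beyond the last carbonyl are
    taken from the spec but only influence atoms that exist; recomputing
    dihedrals on the output reproduces the spec to numerical precision.
    """
    if len(spec) != len(sequence):
        raise PepforgeError("dihedral spec does not cover the sequence")
    aa3s = []
    for aa in sequence:
        if aa not in ONE_TO_THREE:
            raise PepforgeError(f"unknown amino-acid code {aa!r}")
        aa3s.append(ONE_TO_THREE[aa])

    n = len(sequence)
    N = [None] * n
    CA = [None] * n
    C = [None] * n
    N[0] = np.zeros(3)
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N,
                          spec.psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA,
                           spec.omega[i])
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C,
                          spec.phi[i])

    residues = []
    for i, aa3 in enumerate(aa3s):
        O = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                       spec.psi[i] + 180.0)
        backbone = {"N": N[i], "CA": CA[i], "C": C[i], "O": O}
        atoms = [Atom("N", "N", N[i]), Atom("CA", "C", CA[i]),
                 Atom("C", "C", C[i]), Atom("O", "O", O)]
        chi = spec.chi[i] if spec.chi is not None else None
        atoms.extend(_build_side_chain(aa3, backbone, chi))
        residues.append(Residue(aa3, i, atoms))
    return PeptideChain(residues, chain_id, resolution, source_id)


IDEAL_HELIX_PHI = -57.0
IDEAL_HELIX_PSI = -47.0


def make_ideal_helix(sequence: str, chain_id: str = "A",
                     resolution: float | None = None,
                     source_id: str = "helix_fixture",
                     jitter_deg: float = 0.0,
                     rng: np.random.Generator | None = None) -> PeptideChain:
    """Ideal α-helix (φ=−57°, ψ=−47°, ω=180°), optionally with Gaussian
    dihedral jitter to emulate the spread of experimental helices."""
    n = len(sequence)
    phi = np.full(n, IDEAL_HELIX_PHI)
    psi = np.full(n, IDEAL_HELIX_PSI)
    if jitter_deg > 0:
        if rng is None:
            raise PepforgeError("jittered helix requires an rng")
        phi = phi + rng.normal(0.0, jitter_deg, n)
        psi = psi + rng.normal(0.0, jitter_deg, n)
    spec = DihedralSpec(list(phi), list(psi))
    return chain_from_dihedrals(sequence, spec, chain_id, resolution, source_id)


def sample_coil(sequence: str, basins: RamachandranBasins | None = None,
                rng: np.random.Generator | None = None,
                chain_id: str = "A", resolution: float | None = None,
                source_id: str = "coil_fixture",
                max_retries: int = 50) -> PeptideChain:
    """Coil with per-residue (φ, ψ) drawn from a Ramachandran basin mixture.

    Chains failing the heavy-atom clash check are resampled wholesale, up to
    ``max_retries`` times.  Proline φ is pinned to −65°.
    """
    from .assembler import clash_check  # deferred: assembler builds on this module's peers

    basins = basins or RamachandranBasins()
    if rng is None:
        raise PepforgeError("sample_coil requires an rng")
    n = len(sequence)
    for _ in range(max_retries):
        idx = rng.choice(len(basins.weights), size=n, p=np.asarray(basins.weights))
        phi, psi = [], []
        for i, k in enumerate(idx):
            (mphi, mpsi), s = basins.means[k], basins.sigmas[k]
            f = -65.0 if sequence[i] == "P" else float(rng.normal(mphi, s))
            phi.append(f)
            psi.append(float(rng.normal(mpsi, s)))
        chain = chain_from_dihedrals(sequence, DihedralSpec(phi, psi),
                                     chain_id, resolution, source_id)
        ok, _ = clash_check(chain)
        if ok:
            return chain
    raise BuildError(f"could not sample a clash-free coil for {sequence!r} "
                     f"in {max_retries} attempts")


AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_training_set(n_helix: int, n_coil: int, length_range: tuple[int, int] = (5, 20),
                      rng: np.random.Generator | None = None,
                      basins: RamachandranBasins | None = None,
                      helix_jitter_deg: float = 2.0,
                      extra_chains: list[PeptideChain] = ()) -> list[PeptideChain]:
    """Mixture of jittered helices and sampled coils with pseudo-resolutions.

    Sequences are uniform over the 20 standard amino acids, lengths uniform
    over ``length_range`` (inclusive), resolutions uniform on [1.0, 3.0) Å,
    and source ids unique — so resolution-based representative selection and
    sequence dedup are genuinely exercised downstream.
    """
    if rng is None:
        raise PepforgeError("make_training_set requires an rng")
    lo, hi = length_range
    chains: list[PeptideChain] = []
    for j in range(n_helix):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AA_ALPHABET), size=length))
        chains.append(make_ideal_helix(
            seq, resolution=float(rng.uniform(1.0, 3.0)),
            source_id=f"fixh{j:04d}_A", jitter_deg=helix_jitter_deg,
            rng=rng if helix_jitter_deg > 0 else None))
    for j in range(n_coil):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AA_ALPHABET), size=length))
        chains.append(sample_coil(
            seq, basins, rng, resolution=float(rng.uniform(1.0, 3.0)),
            source_id=f"fixc{j:04d}_A"))
    chains.extend(extra_chains)
    return chains
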