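"""Peptide structure data model and PDB input/output.

The in-memory currency of the whole package is :class:`PeptideChain` — an
ordered list of residues, each holding named heavy atoms with Cartesian
coordinates in Å.  Chains are read from PDB text (via :mod:`gemmi`), written
back as plain ATOM/TER records, and filtered for library building with the
same rules used to curate protein-bound peptide training sets: length in
[3, 49], resolution better than 3.0 Å, standard amino acids only, and one
best-resolution representative per unique sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import PDBFormatError

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Heavy side-chain atoms per residue type, PDB v3 nomenclature (no OXT).
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "CYS": ("CB", "SG"),
    "THR": ("CB", "OG1", "CG2"),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "PRO": ("CB", "CG", "CD"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)


def residue_template(aa3: str) -> tuple[str, ...]:
    """Full heavy-atom name set (backbone then side chain) for a residue type."""
    return BACKBONE_ATOMS + SIDE_CHAIN_ATOMS[aa3]


@dataclass(frozen=True)
class Atom:
    """A single named heavy atom."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    """One amino-acid residue: a type plus an ordered, uniquely named atom list."""

    aa3: str
    seq_index: int
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate atom names in residue {self.aa3} {self.seq_index}")

    @property
    def aa1(self) -> str:
        return THREE_TO_ONE.get(self.aa3, "X")

    @property
    def is_standard(self) -> bool:
        return self.aa3 in STANDARD_RESIDUES

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.atoms)

    @property
    def has_backbone(self) -> bool:
        return set(BACKBONE_ATOMS) <= set(self.atom_names)

    @property
    def is_complete(self) -> bool:
        """True when the atom set is exactly the heavy-atom template for the type."""
        if not self.is_standard:
            return False
        return set(self.atom_names) == set(residue_template(self.aa3))

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.aa3} {self.seq_index} has no atom {name!r}")

    def coords(self, names) -> np.ndarray:
        """Stacked coordinates for the requested atom names, in the given order."""
        return np.array([self.atom(n).coord for n in names], dtype=float)

    def with_coords(self, names, coords: np.ndarray) -> "Residue":
        """Copy of this residue with the named atoms moved to new coordinates."""
        table = {n: np.asarray(c, dtype=float) for n, c in zip(names, coords)}
        atoms = [
            replace(a, coord=table[a.name]) if a.name in table else a
            for a in self.atoms
        ]
        return Residue(self.aa3, self.seq_index, atoms)


@dataclass
class PeptideChain:
    """An ordered peptide chain with optional crystallographic resolution."""

    residues: list[Residue]
    chain_id: str = "A"
    resolution: float | None = None
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa1 for r in self.residues)

    @property
    def all_standard(self) -> bool:
        return all(r.is_standard for r in self.residues)

    def transformed(self, transform) -> "PeptideChain":
        """Chain with `transform` (a geometry.Transform) applied to every atom."""
        residues = []
        for res in self.residues:
            atoms = [replace(a, coord=transform.apply(a.coord)) for a in res.atoms]
            residues.append(Residue(res.aa3, res.seq_index, atoms))
        return PeptideChain(residues, self.chain_id, self.resolution, self.source_id)

    def is_peptide_bonded(self, max_cn: float = 2.0) -> bool:
        """True when every consecutive C(i)–N(i+1) distance is below `max_cn` Å."""
        for a, b in zip(self.residues, self.residues[1:]):
            try:
                d = float(np.linalg.norm(a.atom("C").coord - b.atom("N").coord))
            except KeyError:
                return False
            if d >= max_cn:
                return False
        return True


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _validate_atom_records(pdb_text: str) -> None:
    # gemmi is forgiving about malformed numeric fields; reject them up front
    # so callers get a line-numbered error instead of silent garbage.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBFormatError(f"truncated ATOM record at line {lineno}")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBFormatError(
                    f"unparsable coordinate field in ATOM record at line {lineno}"
                ) from None


def read_pdb_peptides(pdb_text: str, chain_filter: str | None = None) -> list[PeptideChain]:
    """Parse PDB text into peptide chains (first model only).

    Hydrogens, waters, HETATM residues and altLoc conformers other than
    blank/'A' are dropped; OXT is dropped; residues are renumbered
    sequentially from 0 with the original numbering retained only inside
    ``source_id`` provenance.  Residues missing backbone atoms remain in the
    chain but report ``is_complete == False``.
    """
    _validate_atom_records(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBFormatError(f"PDB parse failure: {exc}") from exc
    resolution = st.resolution if st.resolution > 0 else None
    chains: list[PeptideChain] = []
    if len(st) == 0:
        return chains
    model = st[0]
    for ch in model:
        if chain_filter is not None and ch.name != chain_filter:
            continue
        residues: list[Residue] = []
        for res in ch:
            if res.is_water() or res.het_flag == "H":
                continue
            atoms: list[Atom] = []
            for atom in res:
                if atom.is_hydrogen():
                    continue
                if atom.altloc not in ("\x00", "", "A"):
                    continue
                if atom.name == "OXT":
                    continue
                if any(existing.name == atom.name for existing in atoms):
                    continue
                atoms.append(
                    Atom(atom.name, atom.element.name,
                         np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                )
            if atoms:
                residues.append(Residue(res.name, len(residues), atoms))
        if residues:
            chains.append(
                PeptideChain(residues, ch.name or "A", resolution,
                             source_id=f"{(st.name or 'pdb').lower()}_{ch.name}")
            )
    return chains


def read_pdb_ensemble(pdb_text: str, chain_filter: str | None = None) -> list[PeptideChain]:
    """Parse a multi-MODEL PDB file into one chain per model (first chain each)."""
    _validate_atom_records(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    conformers: list[PeptideChain] = []
    for model in st:
        text = _model_to_text(model)
        for chain in read_pdb_peptides(text, chain_filter):
            conformers.append(chain)
            break
    return conformers


def _model_to_text(model: gemmi.Model) -> str:
    lines = []
    serial = 0
    for ch in model:
        for res in ch:
            for atom in res:
                serial += 1
                lines.append(_atom_line(serial, atom.name, res.name, ch.name,
                                        res.seqid.num,
                                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                                        atom.element.name, atom.altloc))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _atom_line(serial: int, name: str, resname: str, chain_id: str, resnum: int,
               coord: np.ndarray, element: str, altloc: str = "\x00") -> str:
    if len(name) > 4:
        raise PDBFormatError(f"atom name {name!r} longer than 4 characters")
    # PDB column convention: 1-3 char names start in column 14.
    field = name if len(name) == 4 else f" {name:<3s}"
    alt = altloc if altloc not in ("\x00",) else " "
    x, y, z = (float(v) for v in coord)
    return (f"ATOM  {serial:5d} {field}{alt}{resname:>3s} {chain_id:1s}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}")


def write_pdb(chain: PeptideChain) -> str:
    """Serialize one chain as PDB ATOM records + TER, coordinates to 3 dp."""
    if len(chain) == 0:
        raise PDBFormatError("cannot write an empty chain")
    lines = []
    serial = 0
    for i, res in enumerate(chain.residues, start=1):
        for atom in res.atoms:
            serial += 1
            lines.append(_atom_line(serial, atom.name, res.aa3, chain.chain_id,
                                    i, atom.coord, atom.element))
    last = chain.residues[-1]
    lines.append(f"TER   {serial + 1:5d}      {last.aa3:>3s} {chain.chain_id:1s}{len(chain):4d}")
    return "\n".join(lines) + "\n"


def write_pdb_ensemble(conformers: list[PeptideChain]) -> str:
    """Serialize an ensemble as a multi-MODEL PDB file (one conformer per MODEL)."""
    if not conformers:
        raise PDBFormatError("cannot write an empty ensemble")
    parts = []
    for i, chain in enumerate(conformers, start=1):
        parts.append(f"MODEL     {i:4d}\n{write_pdb(chain)}ENDMDL\n")
    parts.append("END\n")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Dataset filtering
# ---------------------------------------------------------------------------

def dataset_filter(chains: list[PeptideChain], min_len: int = 3, max_len: int = 49,
                   max_resolution: float = 3.0) -> list[PeptideChain]:
    """Curate a peptide set for library building.

    Keeps chains of ``min_len..max_len`` residues, with all-standard residue
    types, resolved better than ``max_resolution`` Å (an absent resolution is
    treated as 0.0 Å, i.e. best); among chains sharing a sequence only the
    best-resolution one is retained (ties broken by ``source_id``).
    """
    def res_key(c: PeptideChain) -> float:
        if c.resolution is None:
            logger.debug("chain %s has no resolution; treating as 0.0 Å", c.source_id)
            return 0.0
        return c.resolution

    eligible = [
        c for c in chains
        if min_len <= len(c) <= max_len and c.all_standard and res_key(c) < max_resolution
    ]
    best: dict[str, PeptideChain] = {}
    order: list[str] = []
    for c in eligible:
        seq = c.sequence
        if seq not in best:
            best[seq] = c
            order.append(seq)
        elif (res_key(c), c.source_id) < (res_key(best[seq]), best[seq].source_id):
            best[seq] = c
    kept = [best[s] for s in order]
    logger.info("dataset_filter: kept %d of %d chains (%d unique sequences)",
                len(kept), len(chains), len(best))
    return kept
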