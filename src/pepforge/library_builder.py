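"""Rotamer and helix-fragment libraries built by RMSD leader clustering.

Four libraries are produced from a curated training set of peptide chains:

* **single-letter** — per amino-acid type, full heavy-atom residue
  conformers aligned on their N/CA/C atoms and clustered on all heavy atoms;
* **C-rotamer** — per ordered dipeptide type, the first residue reduced to
  its backbone (the HEAD anchor) and the second kept in full, clustered
  after HEAD superposition; used to grow a chain toward the C-terminus;
* **N-rotamer** — the mirror image anchored on the second residue's
  backbone (TAIL), used to grow toward the N-terminus;
* **helix** — backbone-only (N, CA, C, O) helical segments keyed by length.

Clustering is greedy leader clustering at a 0.5 Å RMSD threshold with
conformers visited best-resolution-first, so every cluster representative is
simultaneously its founder and its best-resolved member.  A cluster's
probability is its member count divided by the total conformer count for
the key, kept exactly as a ratio of integers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, LibraryError
from .geometry import Transform, kabsch, rmsd_no_fit
from .secondary_structure import assign_ss
from .structure_io import BACKBONE_ATOMS, PeptideChain, residue_template

logger = logging.getLogger(__name__)

CLUSTER_THRESHOLD = 0.5  # Å
MIN_HELIX_FRAGMENT = 4  # one full turn

LIBRARY_FORMAT = "pepforge-library"
LIBRARY_VERSION = 1

_ANCHOR_FRAME_ATOMS = ("N", "CA", "C")


def canonical_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> Transform:
    """Rigid motion placing a residue frame canonically.

    After the transform: CA at the origin, N on the −x axis, C in the
    xy-plane with positive y.  Any fixed frame would do; this one is the
    package convention so stored conformers are directly comparable.
    """
    ex = ca - n
    nx = np.linalg.norm(ex)
    if nx < 1e-8:
        raise GeometryError("canonical frame: N and CA coincide")
    ex = ex / nx
    v = c - ca
    ey = v - np.dot(v, ex) * ex
    ny = np.linalg.norm(ey)
    if ny < 1e-8:
        raise GeometryError("canonical frame: N, CA, C are collinear")
    ey = ey / ny
    ez = np.cross(ex, ey)
    R = np.stack([ex, ey, ez])
    return Transform(R, -R @ ca)


def _res_key(resolution: float | None) -> float:
    return 0.0 if resolution is None else float(resolution)


# ---------------------------------------------------------------------------
# Generic clustering
# ---------------------------------------------------------------------------

@dataclass
class ConformerRecord:
    """One harvested conformer, already in the canonical frame."""

    align_coords: np.ndarray   # superposition anchor atoms
    rmsd_coords: np.ndarray    # atoms entering the cluster RMSD
    resolution: float | None
    source_id: str = ""
    payload: object = None     # opaque; carried to the representative


@dataclass
class Cluster:
    representative: int        # index into the input list
    members: list[int] = field(default_factory=list)


def cluster_conformers(conformers: list[ConformerRecord],
                       threshold: float = CLUSTER_THRESHOLD) -> list[Cluster]:
    """Greedy leader clustering, best resolution first.

    Conformers are visited sorted by (resolution, source_id, harvest order);
    each joins the first cluster whose representative lies within
    ``threshold`` Å (RMSD over ``rmsd_coords`` after superposing
    ``align_coords``), else founds a new cluster.  The founder — by
    construction the best-resolved member — is the representative.
    """
    if not conformers:
        raise LibraryError("cannot cluster an empty conformer list")
    order = sorted(range(len(conformers)),
                   key=lambda i: (_res_key(conformers[i].resolution),
                                  conformers[i].source_id, i))
    clusters: list[Cluster] = []
    for idx in order:
        it = conformers[idx]
        for cl in clusters:
            rep = conformers[cl.representative]
            T, _ = kabsch(it.align_coords, rep.align_coords)
            if rmsd_no_fit(T.apply(it.rmsd_coords), rep.rmsd_coords) < threshold:
                cl.members.append(idx)
                break
        else:
            clusters.append(Cluster(representative=idx, members=[idx]))
    return clusters


# ---------------------------------------------------------------------------
# Library entry types
# ---------------------------------------------------------------------------

@dataclass
class SingleRotamer:
    """Full heavy-atom residue conformer in the canonical frame."""

    aa1: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray         # (k, 3)
    cluster_size: int
    total: int
    resolution: float | None

    @property
    def probability(self) -> float:
        return self.cluster_size / self.total

    def backbone_coords(self, names=_ANCHOR_FRAME_ATOMS) -> np.ndarray:
        idx = [self.atom_names.index(n) for n in names]
        return self.coords[idx]

    def side_chain(self) -> tuple[list[str], list[str], np.ndarray]:
        keep = [i for i, n in enumerate(self.atom_names) if n not in BACKBONE_ATOMS]
        return ([self.atom_names[i] for i in keep],
                [self.elements[i] for i in keep],
                self.coords[keep] if keep else np.zeros((0, 3)))


@dataclass
class DipeptideRotamer:
    """Dipeptide conformer: a 4-atom backbone anchor plus one full residue.

    ``anchor == "head"`` (C-rotamer): anchor is residue 1's backbone, body is
    residue 2.  ``anchor == "tail"`` (N-rotamer): anchor is residue 2's
    backbone, body is residue 1.
    """

    pair: str                  # ordered two-letter type, e.g. "AF"
    anchor: str                # "head" | "tail"
    anchor_coords: np.ndarray  # (4, 3) in N, CA, C, O order
    body_aa1: str
    body_names: tuple[str, ...]
    body_elements: tuple[str, ...]
    body_coords: np.ndarray
    cluster_size: int
    total: int
    resolution: float | None

    @property
    def probability(self) -> float:
        return self.cluster_size / self.total


@dataclass
class HelixFragment:
    """Backbone-only helical fragment; (L, 4, 3) coords in N, CA, C, O order."""

    length: int
    backbone: np.ndarray
    cluster_size: int
    total: int
    resolution: float | None

    @property
    def probability(self) -> float:
        return self.cluster_size / self.total

    @property
    def head_coords(self) -> np.ndarray:
        """N, CA, C of the first residue — the attachment anchor."""
        return self.backbone[0, :3]

    @property
    def tail_coords(self) -> np.ndarray:
        return self.backbone[-1, :3]


@dataclass
class Library:
    single: dict[str, list[SingleRotamer]] = field(default_factory=dict)
    c_rotamer: dict[str, list[DipeptideRotamer]] = field(default_factory=dict)
    n_rotamer: dict[str, list[DipeptideRotamer]] = field(default_factory=dict)
    helix: dict[int, list[HelixFragment]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- lookup helpers used by the assembler ------------------------------
    def singles_for(self, aa1: str) -> list[SingleRotamer]:
        rots = self.single.get(aa1)
        if not rots:
            raise LibraryError(f"no single-letter rotamers for amino acid {aa1!r}")
        return rots

    def _dipeptides_for(self, table: dict, pair: str, body_pos: int, pooled: bool):
        """Exact pair type, else (or when ``pooled``) all pairs sharing the
        body letter, weighted by cluster size."""
        if not pooled:
            rots = table.get(pair)
            if rots:
                return rots, np.array([r.probability for r in rots])
        target = pair[body_pos]
        pool = [r for key, lst in sorted(table.items()) for r in lst
                if key[body_pos] == target]
        if pool:
            w = np.array([r.cluster_size for r in pool], dtype=float)
            return pool, w / w.sum()
        return None, None

    def c_rotamers_for(self, pair: str, pooled: bool = False):
        return self._dipeptides_for(self.c_rotamer, pair, body_pos=1, pooled=pooled)

    def n_rotamers_for(self, pair: str, pooled: bool = False):
        return self._dipeptides_for(self.n_rotamer, pair, body_pos=0, pooled=pooled)

    def helix_lengths(self) -> list[int]:
        return sorted(self.helix)


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------

def _canonicalized_residue(res, transform: Transform) -> tuple[tuple, tuple, np.ndarray]:
    names = residue_template(res.aa3)
    coords = transform.apply(res.coords(names))
    elements = tuple(res.atom(n).element for n in names)
    return names, elements, coords


def build_single_letter_library(chains: list[PeptideChain],
                                threshold: float = CLUSTER_THRESHOLD
                                ) -> dict[str, list[SingleRotamer]]:
    """Cluster complete residues per amino-acid type.

    Conformers are aligned on N/CA/C (canonical frame) and clustered on all
    heavy atoms of backbone and side chain.
    """
    harvested: dict[str, list[ConformerRecord]] = {}
    for chain in chains:
        for res in chain:
            if not res.is_complete:
                continue
            T = canonical_frame(res.atom("N").coord, res.atom("CA").coord,
                                res.atom("C").coord)
            names, elements, coords = _canonicalized_residue(res, T)
            anchor = coords[[names.index(a) for a in _ANCHOR_FRAME_ATOMS]]
            harvested.setdefault(res.aa1, []).append(ConformerRecord(
                anchor, coords, chain.resolution, chain.source_id,
                payload=(names, elements)))
    library: dict[str, list[SingleRotamer]] = {}
    for aa1 in sorted(harvested):
        records = harvested[aa1]
        clusters = cluster_conformers(records, threshold)
        total = len(records)
        rotamers = []
        for cl in clusters:
            rep = records[cl.representative]
            names, elements = rep.payload
            rotamers.append(SingleRotamer(aa1, tuple(names), elements,
                                          rep.rmsd_coords, len(cl.members),
                                          total, rep.resolution))
        library[aa1] = rotamers
    if not library:
        logger.warning("single-letter library is empty (no complete residues)")
    return library


def _build_dipeptide_library(chains: list[PeptideChain], anchor: str,
                             threshold: float) -> dict[str, list[DipeptideRotamer]]:
    harvested: dict[str, list[ConformerRecord]] = {}
    for chain in chains:
        for r1, r2 in zip(chain.residues, chain.residues[1:]):
            if not (r1.is_complete and r2.is_complete):
                continue
            anchor_res, body_res = (r1, r2) if anchor == "head" else (r2, r1)
            T = canonical_frame(anchor_res.atom("N").coord,
                                anchor_res.atom("CA").coord,
                                anchor_res.atom("C").coord)
            anchor_coords = T.apply(anchor_res.coords(BACKBONE_ATOMS))
            names, elements, body_coords = _canonicalized_residue(body_res, T)
            pair = r1.aa1 + r2.aa1
            harvested.setdefault(pair, []).append(ConformerRecord(
                anchor_coords, np.vstack([anchor_coords, body_coords]),
                chain.resolution, chain.source_id,
                payload=(body_res.aa1, names, elements, body_coords)))
    library: dict[str, list[DipeptideRotamer]] = {}
    for pair in sorted(harvested):
        records = harvested[pair]
        clusters = cluster_conformers(records, threshold)
        total = len(records)
        rotamers = []
        for cl in clusters:
            rep = records[cl.representative]
            body_aa1, names, elements, body_coords = rep.payload
            rotamers.append(DipeptideRotamer(
                pair, anchor, rep.align_coords, body_aa1, tuple(names),
                elements, body_coords, len(cl.members), total, rep.resolution))
        library[pair] = rotamers
    return library


def build_c_rotamer_library(chains, threshold: float = CLUSTER_THRESHOLD):
    """Dipeptide rotamers anchored on the first residue's backbone (HEAD)."""
    return _build_dipeptide_library(chains, "head", threshold)


def build_n_rotamer_library(chains, threshold: float = CLUSTER_THRESHOLD):
    """Dipeptide rotamers anchored on the second residue's backbone (TAIL)."""
    return _build_dipeptide_library(chains, "tail", threshold)


def build_helix_library(chains: list[PeptideChain],
                        threshold: float = CLUSTER_THRESHOLD,
                        min_length: int = MIN_HELIX_FRAGMENT
                        ) -> dict[int, list[HelixFragment]]:
    """Backbone-only helix fragments, clustered per length.

    Helical segments are located with :func:`assign_ss`; an assigned run of
    length L contributes exactly one length-L fragment (no sub-windows, so
    per-length probabilities reflect observed run lengths).
    """
    harvested: dict[int, list[ConformerRecord]] = {}
    for chain in chains:
        try:
            ss = assign_ss(chain).states
        except Exception as exc:
            logger.debug("skipping chain %s in helix harvest: %s", chain.source_id, exc)
            continue
        i = 0
        while i < len(ss):
            if ss[i] != "H":
                i += 1
                continue
            j = i
            while j < len(ss) and ss[j] == "H":
                j += 1
            if j - i >= min_length:
                run = chain.residues[i:j]
                first = run[0]
                T = canonical_frame(first.atom("N").coord, first.atom("CA").coord,
                                    first.atom("C").coord)
                backbone = np.stack([T.apply(r.coords(BACKBONE_ATOMS)) for r in run])
                harvested.setdefault(j - i, []).append(ConformerRecord(
                    backbone[0, :3], backbone.reshape(-1, 3),
                    chain.resolution, chain.source_id))
            i = j
    library: dict[int, list[HelixFragment]] = {}
    for length in sorted(harvested):
        records = harvested[length]
        clusters = cluster_conformers(records, threshold)
        total = len(records)
        library[length] = [
            HelixFragment(length,
                          records[cl.representative].rmsd_coords.reshape(length, 4, 3),
                          len(cl.members), total,
                          records[cl.representative].resolution)
            for cl in clusters
        ]
    if not library:
        logger.warning("helix library is empty; generation will fall back to "
                       "per-residue building")
    return library


def build_library(chains: list[PeptideChain],
                  threshold: float = CLUSTER_THRESHOLD,
                  description: str = "") -> Library:
    """Build all four libraries from a (pre-filtered) training set."""
    lib = Library(
        single=build_single_letter_library(chains, threshold),
        c_rotamer=build_c_rotamer_library(chains, threshold),
        n_rotamer=build_n_rotamer_library(chains, threshold),
        helix=build_helix_library(chains, threshold),
        metadata={"threshold": threshold,
                  "training_chains": len(chains),
                  "description": description,
                  "version": LIBRARY_VERSION},
    )
    logger.info("library built: %d aa types, %d C-pairs, %d N-pairs, helix lengths %s",
                len(lib.single), len(lib.c_rotamer), len(lib.n_rotamer),
                lib.helix_lengths())
    return lib


# ---------------------------------------------------------------------------
# Serialization (versioned JSON, coordinates to 4 decimals)
# ---------------------------------------------------------------------------

def _coords_out(a: np.ndarray) -> list:
    return np.round(np.asarray(a, dtype=float), 4).tolist()


def save_library(lib: Library, path) -> None:
    doc = {
        "format": LIBRARY_FORMAT,
        "version": LIBRARY_VERSION,
        "metadata": lib.metadata,
        "single": {
            aa: [{"atom_names": list(r.atom_names), "elements": list(r.elements),
                  "coords": _coords_out(r.coords), "cluster_size": r.cluster_size,
                  "total": r.total, "resolution": r.resolution}
                 for r in rots]
            for aa, rots in sorted(lib.single.items())
        },
        "helix": {
            str(length): [{"backbone": _coords_out(f.backbone),
                           "cluster_size": f.cluster_size, "total": f.total,
                           "resolution": f.resolution}
                          for f in frags]
            for length, frags in sorted(lib.helix.items())
        },
    }
    for key in ("c_rotamer", "n_rotamer"):
        doc[key] = {
            pair: [{"anchor": r.anchor, "anchor_coords": _coords_out(r.anchor_coords),
                    "body_aa": r.body_aa1, "body_names": list(r.body_names),
                    "body_elements": list(r.body_elements),
                    "body_coords": _coords_out(r.body_coords),
                    "cluster_size": r.cluster_size, "total": r.total,
                    "resolution": r.resolution}
                   for r in rots]
            for pair, rots in sorted(getattr(lib, key).items())
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_library(path) -> Library:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise LibraryError(f"cannot read library file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != LIBRARY_FORMAT:
        raise LibraryError(f"{path} is not a {LIBRARY_FORMAT} file")
    if doc.get("version") != LIBRARY_VERSION:
        raise LibraryError(f"library version mismatch: file has "
                           f"{doc.get('version')}, expected {LIBRARY_VERSION}")
    lib = Library(metadata=doc.get("metadata", {}))
    for aa, rots in doc.get("single", {}).items():
        lib.single[aa] = [
            SingleRotamer(aa, tuple(r["atom_names"]), tuple(r["elements"]),
                          np.asarray(r["coords"]), r["cluster_size"], r["total"],
                          r["resolution"])
            for r in rots]
    for key in ("c_rotamer", "n_rotamer"):
        table = getattr(lib, key)
        for pair, rots in doc.get(key, {}).items():
            table[pair] = [
                DipeptideRotamer(pair, r["anchor"], np.asarray(r["anchor_coords"]),
                                 r["body_aa"], tuple(r["body_names"]),
                                 tuple(r["body_elements"]),
                                 np.asarray(r["body_coords"]),
                                 r["cluster_size"], r["total"], r["resolution"])
                for r in rots]
    for length, frags in doc.get("helix", {}).items():
        lib.helix[int(length)] = [
            HelixFragment(int(length), np.asarray(f["backbone"]),
                          f["cluster_size"], f["total"], f["resolution"])
            for f in frags]
    return lib
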