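"""Stochastic fragment-assembly of peptide conformers.

A conformer is grown one residue (or one helix fragment) at a time from the
clustered libraries:

1. the first residue is drawn from the single-letter library;
2. while three or more consecutive predicted states (including the current
   residue) are helical, a backbone helix fragment is drawn by probability,
   grafted onto the current residue's N/CA/C frame, and dressed with
   single-letter side chains;
3. otherwise the next residue comes from the C-rotamer library (N-rotamer
   when building C→N), placed by superposing the rotamer's HEAD backbone on
   the current terminal residue;
4. every attachment passes a heavy-atom clash check; clashes trigger
   redraws, then whole-conformer restarts.

Predicted strand (E) states are built exactly like coil — a single chain
cannot know its cross-strand partner.  No energy model or minimization is
applied; the target of the generator is the protein-bound geometry, which
refinement in isolation tends to move away from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import BuildError, LibraryError
from .fixtures import (ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_C_N_CA, ANGLE_N_CA_C,
                       BOND_C_N, BOND_C_O, BOND_N_CA, BOND_CA_C)
from .geometry import kabsch, place_atom
from .library_builder import (DipeptideRotamer, HelixFragment, Library,
                              SingleRotamer)
from .secondary_structure import SSString
from .structure_io import Atom, ONE_TO_THREE, PeptideChain, Residue

logger = logging.getLogger(__name__)

_BB = ("N", "CA", "C", "O")
_BB_ELEMENTS = ("N", "C", "C", "O")
_FRAME = ("N", "CA", "C")


@dataclass(frozen=True)
class BuildConfig:
    """Assembly parameters; defaults are the package's study conditions."""

    seed: int = 0
    clash_distance: float = 2.0          # Å, heavy-atom severe-clash cutoff
    min_residue_separation: int = 2      # same/adjacent residues exempt
    max_retries_per_step: int = 50
    max_restarts_per_conformer: int = 20
    direction: str = "n_to_c"            # or "c_to_n"
    helix_trigger_run: int = 3           # consecutive H states to trigger a fragment

    def __post_init__(self) -> None:
        if self.clash_distance <= 0 or self.max_retries_per_step <= 0 \
                or self.max_restarts_per_conformer <= 0 or self.helix_trigger_run <= 0:
            raise ValueError("BuildConfig counts and distances must be positive")
        if self.direction not in ("n_to_c", "c_to_n"):
            raise ValueError("direction must be 'n_to_c' or 'c_to_n'")


@dataclass
class Ensemble:
    """Generated conformers in generation order (prefixes are evaluable)."""

    conformers: list[PeptideChain]
    sequence: str
    ss: SSString
    config: BuildConfig
    stats: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.conformers)


# ---------------------------------------------------------------------------
# Clash checking
# ---------------------------------------------------------------------------

def clash_check(chain: PeptideChain, new_residue_indices=None,
                clash_distance: float = 2.0, min_separation: int = 2):
    """Heavy-atom clash audit.

    Fails when any atom pair from residues at least ``min_separation`` apart
    in sequence lies closer than ``clash_distance`` Å.  When
    ``new_residue_indices`` is given, only pairs involving those residues
    are considered (incremental check during assembly).  Returns
    ``(ok, offending)`` with offending tuples
    ``(res_i, atom_i, res_j, atom_j, distance)``.
    """
    coords, res_idx, names = [], [], []
    for ri, res in enumerate(chain.residues):
        for a in res.atoms:
            coords.append(a.coord)
            res_idx.append(ri)
            names.append(a.name)
    if not coords:
        return True, []
    new = set(new_residue_indices) if new_residue_indices is not None else None
    tree = cKDTree(np.asarray(coords))
    offending = []
    for a, b in tree.query_pairs(clash_distance):
        ri, rj = res_idx[a], res_idx[b]
        if abs(ri - rj) < min_separation:
            continue
        if new is not None and ri not in new and rj not in new:
            continue
        d = float(np.linalg.norm(np.asarray(coords[a]) - np.asarray(coords[b])))
        offending.append((ri, names[a], rj, names[b], d))
    return (not offending, offending)


# ---------------------------------------------------------------------------
# Elementary attachment moves
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, items, probs=None):
    if probs is None:
        probs = np.array([it.probability for it in items])
    return items[int(rng.choice(len(items), p=np.asarray(probs)))]


def _residue_from_single(rot: SingleRotamer, seq_index: int, transform=None) -> Residue:
    coords = rot.coords if transform is None else transform.apply(rot.coords)
    atoms = [Atom(n, e, c) for n, e, c in zip(rot.atom_names, rot.elements, coords)]
    return Residue(ONE_TO_THREE[rot.aa1], seq_index, atoms)


def _renumbered(residues: list[Residue]) -> list[Residue]:
    return [Residue(r.aa3, i, r.atoms) for i, r in enumerate(residues)]


def seed_first_residue(sequence: str, lib: Library, rng: np.random.Generator,
                       position: int = 0) -> PeptideChain:
    """Start a chain with a probability-weighted single rotamer draw."""
    aa = sequence[position]
    if aa not in ONE_TO_THREE:
        raise BuildError(f"unknown amino-acid code {aa!r}")
    try:
        rots = lib.singles_for(aa)
    except LibraryError as exc:
        raise BuildError(str(exc)) from exc
    rot = _draw(rng, rots)
    return PeptideChain([_residue_from_single(rot, 0)], source_id="generated")


def extend_with_c_rotamer(chain: PeptideChain, rotamer: DipeptideRotamer,
                          replace_terminal_o: bool = True) -> PeptideChain:
    """Append one residue at the C-terminus.

    The rotamer's HEAD is superposed on the current terminal backbone via
    the N/CA/C frame atoms; the transformed second residue is appended and
    the terminal carbonyl O is re-oriented to the HEAD's transformed O — the
    HEAD carries exactly the carbonyl geometry implied by the following
    residue.  Anchoring on N/CA/C (not O) keeps the peptide bond rigid: the
    terminal O reflects the *previous* dipeptide context and would otherwise
    leak its mismatch into the new bond geometry.
    """
    term = chain.residues[-1]
    Q = term.coords(_FRAME)
    T, _ = kabsch(rotamer.anchor_coords[:3], Q)
    new_res = Residue(ONE_TO_THREE[rotamer.body_aa1], term.seq_index + 1,
                      [Atom(n, e, c) for n, e, c in
                       zip(rotamer.body_names, rotamer.body_elements,
                           T.apply(rotamer.body_coords))])
    residues = list(chain.residues)
    if replace_terminal_o:
        residues[-1] = term.with_coords(["O"], [T.apply(rotamer.anchor_coords[3])])
    residues.append(new_res)
    return PeptideChain(residues, chain.chain_id, chain.resolution, chain.source_id)


def extend_with_n_rotamer(chain: PeptideChain, rotamer: DipeptideRotamer) -> PeptideChain:
    """Prepend one residue at the N-terminus (TAIL-anchored mirror move)."""
    first = chain.residues[0]
    Q = first.coords(_FRAME)
    T, _ = kabsch(rotamer.anchor_coords[:3], Q)
    new_res = Residue(ONE_TO_THREE[rotamer.body_aa1], 0,
                      [Atom(n, e, c) for n, e, c in
                       zip(rotamer.body_names, rotamer.body_elements,
                           T.apply(rotamer.body_coords))])
    residues = _renumbered([new_res] + list(chain.residues))
    return PeptideChain(residues, chain.chain_id, chain.resolution, chain.source_id)


def _graft_side_chain(backbone4: np.ndarray, aa: str, lib: Library,
                      rng: np.random.Generator, seq_index: int) -> Residue:
    """Residue with the given backbone and a grafted single-rotamer side chain."""
    atoms = [Atom(n, e, c) for n, e, c in zip(_BB, _BB_ELEMENTS, backbone4)]
    rot = _draw(rng, lib.singles_for(aa))
    names, elements, side = rot.side_chain()
    if names:
        T, _ = kabsch(rot.backbone_coords(_FRAME), backbone4[:3])
        for n, e, c in zip(names, elements, T.apply(side)):
            atoms.append(Atom(n, e, c))
    return Residue(ONE_TO_THREE[aa], seq_index, atoms)


def extend_with_helix(chain: PeptideChain, fragment: HelixFragment,
                      sequence: str, lib: Library, rng: np.random.Generator,
                      direction: str = "n_to_c") -> PeptideChain:
    """Graft a backbone helix fragment onto the growing terminus.

    The fragment's HEAD (N/CA/C of its first residue; TAIL when building
    C→N) is superposed on the current terminal residue, whose backbone is
    replaced by the fragment's first (last) residue.  Side chains for every
    fragment residue are drawn from the single-letter library and grafted
    onto the fragment backbone.
    """
    L = fragment.length
    if direction == "n_to_c":
        term = chain.residues[-1]
        anchor = fragment.head_coords
        T, _ = kabsch(anchor, term.coords(_FRAME))
        backbone = T.apply(fragment.backbone.reshape(-1, 3)).reshape(L, 4, 3)
        start = term.seq_index
        if start + L > len(sequence):
            raise BuildError("helix fragment overruns the sequence")
        new_res = [_graft_side_chain(backbone[j], sequence[start + j], lib, rng,
                                     start + j) for j in range(L)]
        residues = list(chain.residues[:-1]) + new_res
    else:
        first = chain.residues[0]
        offset = len(sequence) - len(chain)  # sequence position of current first residue
        T, _ = kabsch(fragment.tail_coords, first.coords(_FRAME))
        backbone = T.apply(fragment.backbone.reshape(-1, 3)).reshape(L, 4, 3)
        if offset - (L - 1) < 0:
            raise BuildError("helix fragment overruns the sequence")
        new_res = [_graft_side_chain(backbone[j], sequence[offset - (L - 1) + j],
                                     lib, rng, j) for j in range(L)]
        residues = _renumbered(new_res + list(chain.residues[1:]))
    return PeptideChain(residues, chain.chain_id, chain.resolution, chain.source_id)


_FALLBACK_BASINS = ((-57.0, -47.0), (-120.0, 130.0), (-75.0, 145.0))


def _extend_with_single_fallback(chain: PeptideChain, aa: str, lib: Library,
                                 rng: np.random.Generator) -> PeptideChain:
    """Last-resort C-terminal extension when no dipeptide rotamer exists.

    Builds the next backbone with ideal peptide geometry and Ramachandran
    basin dihedrals, then grafts a single-letter rotamer side chain.
    """
    term = chain.residues[-1]
    N0, CA0, C0 = (term.atom(n).coord for n in _FRAME)
    phi_m, psi_m = _FALLBACK_BASINS[int(rng.integers(len(_FALLBACK_BASINS)))]
    psi = float(rng.normal(psi_m, 10.0))
    phi = float(rng.normal(phi_m, 10.0))
    N1 = place_atom(N0, CA0, C0, BOND_C_N, ANGLE_CA_C_N, psi)
    CA1 = place_atom(CA0, C0, N1, BOND_N_CA, ANGLE_C_N_CA, 180.0)
    C1 = place_atom(C0, N1, CA1, BOND_CA_C, ANGLE_N_CA_C, phi)
    psi_next = float(rng.normal(psi_m, 10.0))
    O1 = place_atom(N1, CA1, C1, BOND_C_O, ANGLE_CA_C_O, psi_next + 180.0)
    O0 = place_atom(N0, CA0, C0, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    residues = list(chain.residues)
    residues[-1] = term.with_coords(["O"], [O0])
    residues.append(_graft_side_chain(np.stack([N1, CA1, C1, O1]), aa, lib, rng,
                                      term.seq_index + 1))
    return PeptideChain(residues, chain.chain_id, chain.resolution, chain.source_id)


# ---------------------------------------------------------------------------
# Full-chain building
# ---------------------------------------------------------------------------

class _StepFailed(Exception):
    pass


def _h_run_length(states: str, i: int) -> int:
    j = i
    while j < len(states) and states[j] == "H":
        j += 1
    return j - i


def _pick_fragment_length(lib: Library, desired: int) -> int | None:
    """Longest available fragment length ≤ desired (None if nothing ≥ 2)."""
    usable = [L for L in lib.helix_lengths() if 2 <= L <= desired]
    return max(usable) if usable else None


def _attempt_step(chain, candidates_fn, new_indices, config, rng, stats,
                  widened_fn=None):
    """Draw/extend/clash-check with bounded redraws.

    When the primary candidate source keeps clashing (sparse libraries can
    make a step nearly deterministic), a second redraw budget is spent on
    ``widened_fn`` — typically the pooled any-first-letter rotamer set —
    before the whole conformer is restarted.
    """
    sources = [candidates_fn] + ([widened_fn] if widened_fn is not None else [])
    for fn in sources:
        for _ in range(config.max_retries_per_step):
            trial = fn()
            ok, _pairs = clash_check(trial, new_indices, config.clash_distance,
                                     config.min_residue_separation)
            if ok:
                return trial
            stats["redraws"] += 1
    raise _StepFailed


def _build_once(sequence: str, states: str, lib: Library, config: BuildConfig,
                rng: np.random.Generator, stats: dict) -> PeptideChain:
    n = len(sequence)
    if config.direction == "c_to_n":
        return _build_once_reverse(sequence, states, lib, config, rng, stats)
    chain = seed_first_residue(sequence, lib, rng)
    if n == 1:
        return chain
    i = 0
    force_coil_until = -1
    while i < n - 1:
        run = _h_run_length(states, i)
        if (i >= force_coil_until and run >= config.helix_trigger_run and lib.helix):
            L = _pick_fragment_length(lib, min(run, max(lib.helix_lengths())))
            if L is not None:
                frags = lib.helix[L]
                chain = _attempt_step(
                    chain,
                    lambda: extend_with_helix(chain, _draw(rng, frags), sequence,
                                              lib, rng, "n_to_c"),
                    range(i, i + L), config, rng, stats)
                if L < run:
                    force_coil_until = i + run  # rest of this run: per-residue
                i += L - 1
                continue
        pair = sequence[i] + sequence[i + 1]
        rots, probs = lib.c_rotamers_for(pair)
        if rots is not None:
            pool, pool_p = lib.c_rotamers_for(pair, pooled=True)
            widened = (None if pool is None or len(pool) <= len(rots) else
                       (lambda: extend_with_c_rotamer(chain, _draw(rng, pool, pool_p))))
            chain = _attempt_step(
                chain,
                lambda: extend_with_c_rotamer(chain, _draw(rng, rots, probs)),
                [i, i + 1], config, rng, stats, widened)
        else:
            logger.debug("no C-rotamers for pair %s; ideal-geometry fallback", pair)
            chain = _attempt_step(
                chain,
                lambda: _extend_with_single_fallback(chain, sequence[i + 1], lib, rng),
                [i, i + 1], config, rng, stats)
        i += 1
    return chain


def _build_once_reverse(sequence, states, lib, config, rng, stats) -> PeptideChain:
    n = len(sequence)
    chain = seed_first_residue(sequence, lib, rng, position=n - 1)
    chain = PeptideChain([Residue(ONE_TO_THREE[sequence[n - 1]], 0,
                                  chain.residues[0].atoms)],
                         source_id="generated")
    i = n - 1  # sequence position of the chain's first residue
    force_coil_until = n
    while i > 0:
        run = 0
        j = i
        while j >= 0 and states[j] == "H":
            run += 1
            j -= 1
        if (i < force_coil_until and run >= config.helix_trigger_run and lib.helix):
            L = _pick_fragment_length(lib, min(run, max(lib.helix_lengths())))
            if L is not None:
                frags = lib.helix[L]
                chain = _attempt_step(
                    chain,
                    lambda: extend_with_helix(chain, _draw(rng, frags), sequence,
                                              lib, rng, "c_to_n"),
                    range(0, L), config, rng, stats)
                if L < run:
                    force_coil_until = i - run  # unreachable positions stay coil
                i -= L - 1
                continue
        pair = sequence[i - 1] + sequence[i]
        rots, probs = lib.n_rotamers_for(pair)
        if rots is None:
            raise BuildError(f"no N-rotamers available for pair {pair!r}")
        pool, pool_p = lib.n_rotamers_for(pair, pooled=True)
        widened = (None if pool is None or len(pool) <= len(rots) else
                   (lambda: extend_with_n_rotamer(chain, _draw(rng, pool, pool_p))))
        chain = _attempt_step(
            chain,
            lambda: extend_with_n_rotamer(chain, _draw(rng, rots, probs)),
            [0], config, rng, stats, widened)
        i -= 1
    return chain


def build_peptide(sequence: str, ss: SSString, lib: Library,
                  config: BuildConfig | None = None,
                  rng: np.random.Generator | None = None) -> PeptideChain:
    """Build one clash-free full-length conformer.

    Deterministic given (sequence, ss, library, config, rng state): redraw
    and restart decisions all consume the same stream.
    """
    config = config or BuildConfig()
    if len(ss) != len(sequence):
        raise BuildError(f"secondary-structure length {len(ss)} != sequence "
                         f"length {len(sequence)}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stats = {"redraws": 0, "restarts": 0}
    for _ in range(config.max_restarts_per_conformer):
        try:
            chain = _build_once(sequence, ss.states, lib, config, rng, stats)
            chain._build_stats = stats  # diagnostic breadcrumb
            return chain
        except _StepFailed:
            stats["restarts"] += 1
    raise BuildError(
        f"failed to build {sequence!r}: {stats['restarts']} restarts, "
        f"{stats['redraws']} redraws exhausted")


def generate_ensemble(sequence: str, ss: SSString, lib: Library, n: int,
                      config: BuildConfig | None = None) -> Ensemble:
    """Generate ``n`` independent conformers from one seeded stream.

    Each conformer uses a substream derived from (seed, conformer index), so
    the ensemble is reproducible and order-independent.
    """
    if n < 1:
        raise BuildError("ensemble size must be >= 1")
    config = config or BuildConfig()
    conformers, stats = [], []
    for k in range(n):
        rng = np.random.default_rng([config.seed, k])
        chain = build_peptide(sequence, ss, lib, config, rng)
        conformers.append(chain)
        stats.append(getattr(chain, "_build_stats", {}))
    return Ensemble(conformers, sequence, ss, config, stats)


def complete_partial(partial: PeptideChain, full_sequence: str, lib: Library,
                     config: BuildConfig | None = None) -> PeptideChain:
    """Extend a partial chain to the full sequence at both termini.

    The partial chain must match exactly one contiguous window of
    ``full_sequence``; its coordinates are left untouched (the C-terminal
    carbonyl is not re-oriented).
    """
    config = config or BuildConfig()
    sub = partial.sequence
    first = full_sequence.find(sub)
    if first < 0:
        raise BuildError("partial sequence does not occur in the full sequence")
    if full_sequence.find(sub, first + 1) >= 0:
        raise BuildError("ambiguous placement: partial sequence occurs more than once")
    rng = np.random.default_rng(config.seed)
    stats = {"redraws": 0, "restarts": 0}
    for _ in range(config.max_restarts_per_conformer):
        try:
            chain = partial
            # C-terminal growth
            for j in range(first + len(sub), len(full_sequence)):
                pair = full_sequence[j - 1] + full_sequence[j]
                rots, probs = lib.c_rotamers_for(pair)
                if rots is None:
                    raise BuildError(f"no C-rotamers for pair {pair!r}")
                pool, pool_p = lib.c_rotamers_for(pair, pooled=True)
                widened = (None if pool is None or len(pool) <= len(rots) else
                           (lambda: extend_with_c_rotamer(
                               chain, _draw(rng, pool, pool_p),
                               replace_terminal_o=False)))
                idx = len(chain)  # chain index of the new residue
                chain = _attempt_step(
                    chain,
                    lambda: extend_with_c_rotamer(chain, _draw(rng, rots, probs),
                                                  replace_terminal_o=False),
                    [idx], config, rng, stats, widened)
            # N-terminal growth
            for j in range(first - 1, -1, -1):
                pair = full_sequence[j] + full_sequence[j + 1]
                rots, probs = lib.n_rotamers_for(pair)
                if rots is None:
                    raise BuildError(f"no N-rotamers for pair {pair!r}")
                pool, pool_p = lib.n_rotamers_for(pair, pooled=True)
                widened = (None if pool is None or len(pool) <= len(rots) else
                           (lambda: extend_with_n_rotamer(chain, _draw(rng, pool, pool_p))))
                chain = _attempt_step(
                    chain,
                    lambda: extend_with_n_rotamer(chain, _draw(rng, rots, probs)),
                    [0], config, rng, stats, widened)
            return PeptideChain(_renumbered(list(chain.residues)), partial.chain_id,
                                partial.resolution, partial.source_id)
        except _StepFailed:
            stats["restarts"] += 1
    raise BuildError(f"clash-irresolvable extension for {full_sequence!r}")
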