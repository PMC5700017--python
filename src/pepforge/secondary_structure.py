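"""Three-state secondary structure: assignment and predicted-string parsing.

``assign_ss`` is a compact Kabsch–Sander style assigner working on backbone
coordinates alone.  Amide hydrogens are reconstructed geometrically (1.0 Å
from N, anti-parallel to the preceding carbonyl), hydrogen bonds scored with
the classic electrostatic model

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol

with a bond called below −0.5 kcal/mol.  Helices come from pairs of
consecutive i→i+4 turns, strands from intra-chain ladder bridges, and helix
runs shorter than four residues are demoted to coil.

``parse_psipred_ss2`` reads the VFORMAT `.ss2` files emitted by common
3-state predictors, so generation can be driven by a predicted string.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PepforgeError
from .structure_io import PeptideChain

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_COUPLING = 0.084 * 332.0
MIN_HELIX_RUN = 4


@dataclass
class SSString:
    """A per-residue 3-state string over {C, H, E}."""

    states: str
    source: str = "user"  # one of assigned / predicted / user
    probabilities: np.ndarray | None = None  # (n, 3) coil/helix/strand, optional

    def __post_init__(self) -> None:
        if set(self.states) - set("CHE"):
            raise PepforgeError(f"secondary-structure alphabet is C/H/E, got {self.states!r}")

    def __len__(self) -> int:
        return len(self.states)

    def __str__(self) -> str:
        return self.states


def _backbone_arrays(chain: PeptideChain) -> tuple[np.ndarray, ...]:
    missing = [i for i, r in enumerate(chain.residues) if not r.has_backbone]
    if missing:
        raise PepforgeError(f"incomplete backbone at residues {missing}")
    N = np.array([r.atom("N").coord for r in chain])
    CA = np.array([r.atom("CA").coord for r in chain])
    C = np.array([r.atom("C").coord for r in chain])
    O = np.array([r.atom("O").coord for r in chain])
    return N, CA, C, O


def _hbond_matrix(N, C, O) -> np.ndarray:
    """hb[a, d] — True when CO of residue a accepts an H-bond from NH of d."""
    n = len(N)
    # Amide H of residue d (d >= 1): along the previous carbonyl C->O reversed.
    H = np.full((n, 3), np.nan)
    for d in range(1, n):
        u = C[d - 1] - O[d - 1]
        H[d] = N[d] + u / np.linalg.norm(u)
    hb = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for d in range(1, n):
            if abs(a - d) < 2:
                continue
            r_on = np.linalg.norm(O[a] - N[d])
            r_oh = np.linalg.norm(O[a] - H[d])
            r_cn = np.linalg.norm(C[a] - N[d])
            r_ch = np.linalg.norm(C[a] - H[d])
            if min(r_on, r_oh, r_cn, r_ch) < 0.5:
                continue  # atoms essentially fused; not a hydrogen bond
            e = _COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hb[a, d] = e < HBOND_ENERGY_CUTOFF
    return hb


def assign_ss(chain: PeptideChain) -> SSString:
    """Assign C/H/E states from backbone geometry.

    Requires ≥ 3 residues with complete backbones; raises listing offending
    residues otherwise.  The assignment is invariant under rigid motion.
    """
    if len(chain) < 3:
        raise PepforgeError("secondary-structure assignment needs at least 3 residues")
    N, CA, C, O = _backbone_arrays(chain)
    n = len(chain)
    if n < 5:
        return SSString("C" * n, source="assigned")
    hb = _hbond_matrix(N, C, O)

    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        turn4[i] = hb[i, i + 4]
    states = ["C"] * n
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            for r in range(i, i + 4):
                states[r] = "H"

    # Ladder bridges (single chain, |k-l| >= 3): parallel or antiparallel.
    def _hb(a, d):
        return 0 <= a < n and 0 <= d < n and hb[a, d]

    for k in range(n):
        for l in range(k + 3, n):
            para = (_hb(k - 1, l) and _hb(l, k + 1)) or (_hb(l - 1, k) and _hb(k, l + 1))
            anti = (_hb(k, l) and _hb(l, k)) or (_hb(k - 1, l + 1) and _hb(l - 1, k + 1))
            if para or anti:
                for r in (k, l):
                    if states[r] == "C":
                        states[r] = "E"

    # Demote helix runs shorter than one full turn.
    i = 0
    while i < n:
        if states[i] == "H":
            j = i
            while j < n and states[j] == "H":
                j += 1
            if j - i < MIN_HELIX_RUN:
                for r in range(i, j):
                    states[r] = "C"
            i = j
        else:
            i += 1
    return SSString("".join(states), source="assigned")


_SS2_STATE_MAP = {"C": "C", "H": "H", "E": "E"}


def parse_psipred_ss2(text: str, expected_sequence: str | None = None) -> SSString:
    """Parse PSIPRED VFORMAT `.ss2` output into an :class:`SSString`.

    Rows are ``index aa state p_C p_H p_E``; header/comment lines are
    ignored.  When ``expected_sequence`` is given, both the row count and
    the amino-acid column must match it.
    """
    states = []
    aas = []
    probs = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if not fields[0].isdigit():
            continue  # header such as "PSIPRED VFORMAT ..."
        if len(fields) < 6:
            raise PepforgeError(f".ss2 parse error at line {lineno}: expected 6 columns")
        _, aa, state = fields[0], fields[1], fields[2]
        if state not in _SS2_STATE_MAP:
            raise PepforgeError(f".ss2 parse error at line {lineno}: state {state!r}")
        try:
            probs.append([float(x) for x in fields[3:6]])
        except ValueError:
            raise PepforgeError(f".ss2 parse error at line {lineno}: bad probability") from None
        states.append(_SS2_STATE_MAP[state])
        aas.append(aa)
    if not states:
        raise PepforgeError("no residue rows found in .ss2 input")
    if expected_sequence is not None and "".join(aas) != expected_sequence:
        raise PepforgeError(
            f".ss2 sequence {''.join(aas)!r} does not match expected {expected_sequence!r}")
    return SSString("".join(states), source="predicted",
                    probabilities=np.asarray(probs))


def all_coil(sequence: str) -> SSString:
    """Trivial fallback predictor: every residue coil."""
    return SSString("C" * len(sequence), source="predicted")
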