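# Methods

This note records the model, its tunable parameters, the numerical choices,
and the points where the design was genuinely open — in enough detail that a
maintainer can predict the code's behavior without reading it.

## Model overview and assumptions

The generator treats a peptide as a chain assembled from empirical building
blocks: residue conformers (rotamers) and backbone helix fragments harvested
from previously observed peptide structures. The central assumptions are:

1. **Local geometry is transferable.** A dipeptide conformation observed in
   one peptide is a valid local step in another; chaining such steps with
   rigid superposition produces realistic backbones without any energy
   model.
2. **Secondary structure is informative but coarse.** Predicted helical runs
   are built from whole backbone fragments (helices are stable and largely
   sequence-independent, so fragments store no side chains); coil and strand
   states are built residue-by-residue. A single chain cannot know its
   cross-strand partner, so strand (E) states are treated like coil — a
   known limitation for peptides that form β-sheets with their receptor.
3. **The target is the bound geometry.** No minimization is applied: relaxing
   a peptide in isolation moves it toward its free-state minimum and away
   from bound-like conformations, which is the opposite of what ensemble
   docking needs.

## Library construction

- **Curation** (`dataset_filter`): length 3–49, all-standard residues,
  resolution strictly better than 3.0 Å; among equal sequences the
  best-resolution chain wins (ties broken by source id so the outcome is
  deterministic). A chain with no resolution record is treated as 0.0 Å —
  "best" — so synthetic references deterministically win representative
  selection; this is logged.
- **Clustering**: greedy leader clustering at **0.5 Å** RMSD. Conformers are
  visited sorted by (resolution, source id, harvest order); each joins the
  first cluster whose representative is within threshold, else founds a new
  cluster. This makes the representative simultaneously the founder and the
  best-resolution member, runs in O(n·k), and is exactly reproducible.
  Cluster probability is the member count over the per-key total, stored as
  an exact ratio of integers.
- **Anchors**: single rotamers are canonicalized by their own N/CA/C frame
  (CA at origin, N on −x, C in the xy-plane with +y — any fixed frame works;
  this one is the package convention). C-rotamers are canonicalized by the
  first residue's frame and clustered after superposing the 4-atom HEAD
  (N, CA, C, O); N-rotamers mirror this on the second residue; helix
  fragments use the first residue's frame and cluster on all backbone atoms.
- **Dipeptide cluster RMSD atoms**: all retained heavy atoms (HEAD backbone
  plus the full second residue), mirroring the single-letter "all heavy
  atoms" rule.
- **Helix harvesting**: an assigned helical run of length L ≥ 4 (one full
  turn) contributes exactly one length-L fragment — no sub-windows — so
  per-length probabilities reflect observed run lengths rather than window
  counts.

## Secondary-structure assignment

A compact Kabsch–Sander style assigner: amide H rebuilt 1.0 Å from N along
the preceding C=O direction; hydrogen-bond energy
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with a bond
below **−0.5 kcal/mol** (the classic default); helix from two consecutive
i→i+4 turns, strand from intra-chain ladder bridges (|i−j| ≥ 3), helix runs
shorter than 4 demoted to coil. The assignment surface is agreement with
DSSP-style behavior on ideal fixtures, not bit-compatibility with any
particular binary. Prediction is not performed internally: generation takes
a user string or a PSIPRED `.ss2` file; an all-coil fallback exists for
smoke tests.

## Assembly

- **Attachment transform**: rotamers and fragments are placed by Kabsch
  superposition of the anchor's **N/CA/C** atoms onto the current terminal
  residue. The anchor's O is *excluded from the fit* deliberately: the
  terminal carbonyl belongs to the previous attachment's context, and
  fitting through it leaks that mismatch into the new peptide bond (bond
  lengths drift up to ~2 Å in testing). After placement the terminal O is
  overwritten by the anchor's transformed O — carbonyl orientation is
  determined by the *following* residue, which is exactly what the HEAD
  carries.
- **Helix steps**: triggered by ≥ `helix_trigger_run` (default 3)
  consecutive H states including the current residue. Fragment length is
  the run length capped at the longest library length; if that exact length
  is absent the nearest shorter one is used, and the remainder of the run is
  built per-residue (fragments never chain within one run). Side chains for
  every fragment residue are drawn from the single-letter library and
  grafted by superposing the rotamer's N/CA/C on the fragment backbone.
- **Clash model**: "severe clash" = any heavy-atom pair under
  `clash_distance` (default **2.0 Å**) between residues ≥ 2 apart in
  sequence. Permissive enough for deliberately unminimized coarse models,
  strict enough to forbid genuine atom overlap. Incremental checks cover
  the newly placed residues *and* the re-oriented terminal carbonyl.
- **Retry policy**: per step up to `max_retries_per_step` (50) redraws from
  the step's own candidate set; if a sparse library makes the step nearly
  deterministic (singleton pair types), a second equal budget redraws from
  the pooled set of all rotamers sharing the body residue type; then the
  whole conformer restarts, up to `max_restarts_per_conformer` (20). The
  same pooling serves as the fallback when a pair type is entirely absent,
  and an ideal-geometry single-rotamer placement is the last resort.
- **Randomness**: one `numpy` generator seeded per conformer from
  (ensemble seed, conformer index), so ensembles are reproducible and
  order-independent; all redraw/restart decisions consume the same stream.
- **Direction**: N→C with C-rotamers by default; C→N with N-rotamers is
  symmetric. Partial-structure completion grows C-terminal with C-rotamers
  and N-terminal with N-rotamers and never moves existing atoms (the
  terminal O is left as-is there).

## Evaluation

cRMSD (Cα) is the default accuracy measure; bRMSD and aRMSD are available.
aRMSD pairs atoms by name with no symmetry correction for e.g. PHE CD1/CD2 —
documented so results are reproducible. Best-fit RMSD is evaluated on
ensemble prefixes (generation order), making accuracy-versus-size curves a
single pass. Success uses `rmsd_C(n) = 1.0·[1 + ln(n/3)]` Å (natural log;
the printed anchor values 1.0 Å at n=3 and 3.3 Å at n=30 force the base).
RMSDs are reported to 2 decimals and cutoffs to 1 in the CLI; full precision
is kept internally. Superposition of 3 Cα atoms is permitted; collinear
point sets raise instead of proceeding.

## Synthetic data

The fixture generator emulates a curated experimental training set:

- backbones built by NeRF internal→Cartesian extension with standard bond
  geometry (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å); requested
  dihedrals are recovered from the output to < 1e-4°;
- side chains from a built-in ideal-geometry table with χ angles at common
  rotamer values (chemically plausible, not rotamer-census-faithful; the
  proline ring is approximate and proline φ is pinned to −65°);
- helices at (φ, ψ) = (−57°, −47°), optionally jittered (training-set
  default σ = 2°) so same-length helices do not collapse to one cluster;
- coils drawn per residue from a Ramachandran basin mixture — α (−57, −47,
  σ=10°), β (−120, 130, σ=15°), PPII (−75, 145, σ=10°) with weights
  0.30/0.40/0.30, a generic coil-region balance — resampled wholesale on
  clash failure;
- pseudo-resolutions uniform on [1.0, 3.0) Å and unique source ids, so
  resolution-based representative selection and sequence dedup are
  genuinely exercised.

What passing tests on these fixtures do **not** show: real side-chain
rotamer statistics, sequence-dependent backbone preferences, β-structure
formed against a receptor, or experimental coordinate noise. They do show
that the harvesting, clustering, assembly and scoring machinery is
geometrically and probabilistically correct, and that a conformation present
in the training set is recovered from it.

## Problem sizes in the default test run

Fixture training sets of ~25–30 chains (lengths 5–12 or 5–20), ensembles of
60–400 conformers per peptide and a 1000-conformer validity audit keep the
full suite around a quarter minute on one CPU while still covering every
code path, including the helix trigger and the sparse-library fallbacks.

## Known limitations

- Strand states build like coil; β-hairpin closure is not constrained.
- Rotamer probabilities are not conditioned on backbone φ/ψ bins
  (no Dunbrack-style dependence).
- No energetics anywhere: conformers can contain strained torsions; users
  docking against a specific receptor may minimize afterwards.
- Multi-model NMR input, mmCIF, hydrogens and ligands are out of scope;
  altLoc conformers other than blank/'A' are dropped on read.
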