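# Library file schema

Libraries are stored as a single versioned JSON document (coordinates in Å,
rounded to 4 decimals). Probabilities are *not* stored: every entry carries
`cluster_size` and `total`, and the probability is their exact ratio.

```jsonc
{
  "format": "pepforge-library",      // required magic
  "version": 1,                      // loader rejects other versions
  "metadata": {
    "threshold": 0.5,                // clustering RMSD threshold, Å
    "training_chains": 70,
    "description": "free text",
    "version": 1
  },

  // single-letter rotamers, keyed by one-letter amino-acid code.
  // Coordinates are in the canonical residue frame:
  // CA at the origin, N on the -x axis, C in the xy-plane (y > 0).
  "single": {
    "A": [
      {
        "atom_names": ["N", "CA", "C", "O", "CB"],
        "elements":   ["N", "C",  "C", "O", "C"],
        "coords":     [[-1.458, 0.0, 0.0], ...],   // one 3-vector per atom
        "cluster_size": 12,
        "total": 30,
        "resolution": 1.42                          // Å; null if unknown
      }
    ]
  },

  // dipeptide rotamers, keyed by the ordered two-letter pair type.
  // "anchor" is "head" (first residue's backbone; C-rotamer) or "tail"
  // (second residue's backbone; N-rotamer).  anchor_coords are the 4
  // backbone atoms in N, CA, C, O order, in the anchor residue's canonical
  // frame; body_* describe the full retained residue in the same frame.
  "c_rotamer": {
    "AF": [
      {
        "anchor": "head",
        "anchor_coords": [[...], [...], [...], [...]],
        "body_aa": "F",
        "body_names": ["N", "CA", "C", "O", "CB", "CG", ...],
        "body_elements": ["N", "C", ...],
        "body_coords": [[...], ...],
        "cluster_size": 3, "total": 7, "resolution": 2.1
      }
    ]
  },
  "n_rotamer": { /* same entry shape, anchor == "tail" */ },

  // backbone-only helix fragments keyed by residue count (as a string,
  // JSON requires string keys).  "backbone" is length x 4 x 3 in
  // N, CA, C, O order, in the first residue's canonical frame.
  "helix": {
    "12": [
      { "backbone": [[[...], [...], [...], [...]], ...],
        "cluster_size": 2, "total": 5, "resolution": 1.8 }
    ]
  }
}
```

Loading an empty/truncated file, a document without the magic `format`
string, or a different `version` raises `LibraryError`.
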