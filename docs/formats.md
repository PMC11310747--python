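# File formats

## Structure input

### PDB (v3.3 fixed columns)

`read_pdb` parses `ATOM`/`HETATM` records only, by 1-based column:

| field | columns |
|---|---|
| atom name | 13–16 |
| altloc | 17 |
| residue name | 18–20 |
| x, y, z (Å) | 31–38, 39–46, 47–54 |
| occupancy | 55–60 (blank → 1.0) |
| element | 77–78, falling back to the alphabetic part of the atom name |

Altloc policy: for each atom name the highest-occupancy conformer is kept
(ties resolved to `A`, then blank).  Waters (`HOH`/`WAT`/`DOD`/`H2O`) are
excluded by default.  Coordinates are treated as orthogonal Å; there is no
CIF/cell handling — fragments are expected pre-extracted.  Malformed
records raise `ParseError` with the line number.

### SD / MOL (V2000)

`read_sdf` parses V2000 connection tables: the counts line at fixed
3-column fields, atoms at 10-column coordinate fields with the element at
columns 32–34, the bond block, and multi-record files split on `$$$$`.
V3000 markers raise an explicit unsupported-dialect error; truncated
tables and count mismatches raise `ParseError` with line numbers.

### XYZ

Count line, comment line, then `element x y z` rows; count mismatches are
rejected.  `write_xyz` emits 6-decimal coordinates (round trips preserve
coordinates at that precision).

Hydrogens are parsed by all readers and dropped by default before
decomposition (`include_h=True` keeps them).

## JSON schemas (versioned)

### Model — `symcoord.model/1`

```json
{
  "schema": "symcoord.model/1",
  "name": "anthracene",
  "group": "D2h",
  "elements": ["C", "..."],
  "coords": [["-2.424871", "1.400000", "0.000000"], ["..."]],
  "bonds": [[0, 1, 1]],
  "perms": {"E": [0, 1], "C2(z)": [10, 13]},
  "provenance": "built from ..."
}
```

Coordinates are decimal strings with 6 places, making save→load→save
round trips byte-identical.  `perms` maps each operation label to the
cached atom permutation; if absent or incomplete it is recomputed on load
with a warning.  Schema violations raise `SchemaError` carrying the JSON
path of the offending field.

### Decomposition result — `symcoord.result/1`

Top-level fields: `group`, `structure_id`, `model_used`, `elements`,
`aligned_coords`, `model_coords`, `reconstruction_residual`, `transform`
(rotation matrix, translation, objective), `magnitudes` (irrep → Å), and
`modes` — the totally symmetric mode followed by every reported mode, each
with its irrep label, orientation tag (degenerate variants), magnitude and
per-atom vectors.

### Principal modes — `symcoord.pca/1`

`irrep`, orthonormal `components` (k × 3N), `explained_variance`
fractions, per-structure `coefficients` and `residuals`, and the structure
`ids`.

### Point-group table — `symcoord.point_group/1`

Operations as `{kind, axis, order, power, label}` and irreps as
`{label, characters, degeneracy, parity, variants, variant_angles,
basis}`; loading validates the document against the canonical table
bit-exactly.

## Tabular outputs

* Magnitude table CSV: one row per irrep, `Sum (Å)` column, two decimals
  (decimal half-up).
* Collection outputs: `magnitudes.csv` (structures × irreps),
  `coefficients.csv` (PCA amplitudes + residual), `nearest.csv` (ranked
  squared distances of magnitude vectors), `pca.json`.
* Mode-vector export (`write_vectors_xyz`): one row per atom — element,
  aligned coordinates, then one displacement triple per reported mode.
* Mondrian diagrams as standalone SVG, 3-decimal float formatting,
  byte-stable for identical input.
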