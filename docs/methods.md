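# Methods

## Model

`resglyph` renders a protein as one glyph per residue. A glyph is a rigid
frame (origin + right-handed orthonormal axes) plus shape-specific
dimensions and per-part colors. The mapping residue → (family, shape,
colors) is a fixed dictionary; the fit of each glyph to the coordinates is
purely geometric and uses heavy atoms only — hydrogens are parsed (they are
needed to detect histidine protonation) but never enter a fit.

### Classification

The 20 standard residues partition into five families: hydrophobic
(G, A, V, L, I, M, F, W), neutral polar (S, T, C, N, Q, Y, H), positive
(K, R), negative (D, E), and proline. Tyrosine and histidine sit in the
neutral-polar family even though they carry rings; their glyphs are ring
prisms. Unknown 3-letter codes are non-standard and drawn as orange stars;
chemically modified residues that occur inline in chains (MSE, SEP, PTR, …)
are treated as polymer but classify as non-standard. Histidine force-field
variants (HID/HIE/HSD/HSE neutral, HIP/HSP protonated) count as histidine.

The grammar fixes color *names* only; the RGBA constants live in
one palette table (`dictionary.py`) and in the shipped
`data/dictionary.yaml`. Darker shades keep the hue and reduce value. The
body color of neutral-polar glyphs (pyramids, amide prisms, the Tyr
hexagon) is not prescribed anywhere; gray was chosen as the family color so
that the accent parts (red/yellow tips, split base faces) remain the salient
signal. Asp/Glu bodies are red (the negative family color) with a darker-red
base face.

### Geometric fits

* **Principal frame** (ellipsoids, elongation axes): eigenvectors of the
  side-chain point covariance, ordered by decreasing eigenvalue; extents are
  half-ranges of the projections. The first axis is signed toward
  Cα→centroid, the second by a fixed global convention (+z, then +y, +x),
  and the third flipped if needed for det +1.
* **Ring plane** (Phe/Tyr/Trp/His): centroid of the named ring atoms plus
  the smallest-eigenvalue direction of their covariance (least-squares
  plane); the circumradius is the largest atom distance from the centroid.
  Trp uses the six-membered ring for the plane and covers the rest of the
  indole by elongation — one prism, not two fused rings.
* **Polar apex** (Ser/Thr/Cys): unit vector Cα→OG/OG1/SG.
* **Amide/carboxylate prisms** (Asn/Gln/Asp/Glu): base-face center is the
  midpoint of the two terminal polar atoms; the base normal is the sp2
  group-plane normal (cross product over the C, O, N/O atoms); local x
  points toward the oxygen, which orients the red/blue split of the amide
  base face.
* **Cuboids** (Lys/Arg): long axis Cα→terminal-group centroid (NZ for Lys,
  the NH1/NH2/NE guanidinium centroid for Arg). The transverse axes are the
  principal directions of the side-chain scatter projected perpendicular to
  the long axis — a data-driven choice, so the whole frame (and therefore
  the cross-section extents) is equivariant under rigid motions up to axis
  signs; a fixed global perpendicular would not be.
* **Spheres/cubes/stars** are anchored on single atoms (Cα, or Cβ for Ala);
  their in-plane orientation is cosmetic. The star's plane normal follows
  Cα→Cβ when Cβ exists, else +z — the orientation of a star "on top of the
  Cα" is not otherwise determined.

Sign conventions (global-axis tie-breaks) make every build bitwise
deterministic; they are cosmetic for closed shapes. Under a rigid transform
all origins move exactly, data-driven axes rotate up to sign, and all
dimensions are invariant (validated to 1e-6 in the tests).

### Sizing

The grammar only demands that elongation follow the side-chain dimensions;
the constants are this package's choices, collected in `SizingConfig`
(all Å): ellipsoid padding 0.8 with a 0.8 minimum semi-axis; ring-prism
circumradius padding 0.6 and half-thickness 0.5; pyramid base half-width 1.0
and height = |Cα→polar| + 0.5, with the apex 30 % colored as the tip; cuboid
padding 0.7; cube half-edge 0.9; Gly sphere 1.0, Ala 1.3; star outer radius
1.2, inner/outer ratio 0.45, half-thickness 0.3. The Met band covers the
outer 20 % of the major axis at the pole nearest SD; the Tyr rim segment
spans the 60° sector toward OH.

A padded bounding box does not bound the *ellipsoid* norm of the atoms (a
corner atom can exceed 1), so ellipsoid semi-axes are additionally rescaled
by the maximum ellipsoid norm when it exceeds 1; this makes the containment
guarantee (all side-chain atom centers inside the surface) hold by
construction for ellipsoids and cuboids. Ellipsoid and cuboid origins are
the mid-range centers of the projections, not the centroid, for the same
reason.

### Degraded fallback

If a shape rule's atoms are missing the glyph degrades to a 1.0 Å sphere at
Cα in the family base color, flagged `degraded`; if even Cα is absent the
residue is skipped with a warning. Both counts are reported by the CLI
`--summary`.

### Structure input

Parsing is delegated to gemmi (PDB dialect only; the reader is the single
entry point where mmCIF could be added). Alternate locations keep the
highest occupancy, ties going to the smallest altloc letter. Residues are
ordered by (chain, sequence number, insertion code). Waters are non-polymer;
HETATM residues are polymer only if their code is standard or a known inline
modification. Out-of-range occupancies are clamped to [0, 1] with a warning.
Models of a multi-MODEL file must share a residue key set; if not, the
intersection is kept with a warning so per-frame scenes stay aligned.

### Zone selection

A residue is in the zone of a reference entity iff *any* of its heavy atoms
is within the cutoff (Euclidean, boundary-inclusive) of *any* reference
atom — atom-wise, not residue-center-wise, matching common viewer "zone"
semantics. Reference residues are excluded from their own zone. Along
ensembles the zone is re-evaluated per frame by default (a moving ligand has
a moving neighborhood) or frozen to frame 0 on request.

## Export

Tessellation produces watertight, outward-wound triangle meshes with
per-face part labels. Spheres and ellipsoids are icospheres (subdivision
level 3 by default, which keeps the ellipsoid mesh volume within ~1 % of
(4/3)πabc; level 2 is ~3.4 % low because the inscribed polyhedron
underestimates); prisms, pyramids, boxes and stars are exact. OBJ carries
color through MTL materials (one per distinct RGBA) since OBJ has no
per-face color; BILD prints all numbers at 3 decimals and uses native
`.sphere`/`.box` commands where exact, `.polygon` triangles otherwise; the
JSON schema dumps glyph parameters (not meshes) and round-trips losslessly.
All writers are deterministic: identical scenes give byte-identical files.
Transparency is a per-scene or per-glyph alpha override applied at export.

## Synthetic fixtures

The fixtures module generates every structure the tests need. Residue
templates are built from internal coordinates with canonical values (Cα–Cβ
1.53 Å, aromatic bonds 1.39–1.40 Å, exactly planar rings via 2-D layouts
mapped into 3-D); chemical accuracy beyond bond lengths and planarity is
irrelevant to glyph fitting and not pursued. Peptides place residues on a
straight axis at a fixed spacing (default 5 Å; 8 Å for complexes) instead of
real φ/ψ geometry — this exercises every glyph and makes zone constructions
solvable: the one-atom ligand of `synthetic_complex` is positioned by a
deterministic grid search so that *exactly* the requested residues fall in
its 8 Å zone (widely separated contact sets are geometrically infeasible for
a single atom and raise an error). Ensembles are seeded Gaussian jitters of
the same peptide.

What the fixtures do not emulate: real backbone conformation, rotamer
distributions, crystallographic disorder beyond simple altloc cases, or
experimental noise. Passing tests therefore demonstrate the correctness of
the classification, fitting and export machinery, not robustness to
pathological experimental structures.

## Problem sizes

The test suite and `scripts/acceptance.py` use 10–21-residue synthetic
peptides, 100 random point sets per geometric oracle, and 10 random rigid
motions over the full residue set — sizes at which every oracle can be
brute-forced exactly while covering all 21 template residues and all nine
shape kinds.

## Known limitations

* PDB input only (no mmCIF), no symmetry/assembly expansion.
* No glyphs for ligands, solvents or ions — they serve only as zone
  references.
* Trp is one elongated hexagonal prism, not a two-ring figure.
* Fully deprotonated histidine cannot be inferred from standard PDB naming;
  it is reachable only via explicit hydrogens or a user override.
* The palette is a rendering choice; viewers that ignore MTL alpha will
  drop transparency.
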