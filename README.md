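# resglyph

**Residue-level glyph scenes for protein structures.**

Full-atom renderings of proteins are crowded, and coarse-grained ones throw
away the side-chain shapes and chemistry that explain interactions. `resglyph`
implements a middle layer: a *visual dictionary* that replaces every amino-acid
side chain with one colored geometric primitive fitted to its atomic
coordinates, so hydrophobic patches, charged clusters and binding-site
chemistry can be read off a structure at a glance. Scenes are exported in
portable formats (Wavefront OBJ/MTL, Chimera-family BILD, JSON) and can be
overlaid on any viewer's ribbon or atomic rendering. It is aimed at structural
biologists and modellers inspecting static structures or molecular-dynamics
ensembles.

## The grammar

Residues are partitioned into five physicochemical families — hydrophobic (8),
neutral polar (7), positively charged (2), negatively charged (2), and proline
— with colors following chemistry conventions (green hydrophobic, dark blue
positive, red negative) and shapes echoing the side-chain geometry:

| residues | glyph | placement |
|---|---|---|
| Gly, Ala | sphere | on Cα (Gly) / Cβ (Ala) |
| Val, Leu, Ile, Met | ellipsoid | principal axes of the side chain; Met gets a yellow band at the S pole |
| Phe, Trp, Tyr | hexagonal prism | least-squares ring plane, elongated along the side chain's in-plane axis; Tyr's rim is red at the hydroxyl |
| Ser, Thr, Cys | pyramid | base centered on Cα, apex along Cα→O/S; tip red (OH) or yellow (SH) |
| Asn, Gln / Asp, Glu | triangular prism | base face on the amide/carboxylate group; split red/blue (amides) or darker red (acids) |
| His | pentagonal prism | on the imidazole ring; aquamarine, dark blue when protonated, red when deprotonated |
| Lys, Arg | cuboid | long axis Cα→charged group; darker blue end face at the charge |
| Pro | small gray cube | on Cα |
| anything else | orange star | on Cα |

Histidine protonation is read from force-field residue names (HID/HIE/HIP...),
from explicit ring-nitrogen hydrogens, or set per residue by the user. Glyph
sizes follow the side-chain dimensions (details in `docs/methods.md`); every
constant is configurable, and the whole dictionary ships as editable YAML
(`resglyph dict`).

## Worked example

Generate a synthetic peptide–ligand complex where residues 4–5 contact the
ligand, then render the 8 Å zone around it:

```sh
resglyph fixtures --sequence ACDEFGHIKL --complex-contacts 4,5 --out complex.pdb
resglyph render complex.pdb --select zone:LIG:8.0 --out zone.bild --summary
```

which prints

```
rendered=2 degraded=0 skipped=0
```

— two residues have a heavy atom within 8 Å of the ligand, both produced a
full-quality glyph. The same scene from Python:

```python
from resglyph import build_scene, parse_selection, read_structure

model = read_structure("complex.pdb").models[0]
scene = build_scene(model, parse_selection("zone:LIG:8.0"))
for g in scene.glyphs:
    chain, seq, icode, name3 = g.residue_key
    print(chain, seq, name3, g.spec.shape.value, g.dimensions)
```

```
A 4 GLU triangular_prism {'circumradius': 1.70..., 'half_thickness': 0.5}
A 5 PHE hexagonal_prism {'circumradius': 1.99..., 'half_thickness': 0.5, 'half_length': 3.49...}
```

Glu 4 is drawn as a red triangular prism whose base face sits on the
carboxylate oxygens; Phe 5 as a green hexagonal prism on its ring, elongated
to 3.5 Å half-length to cover Cβ. The `zone.bild` file opens directly in
Chimera-family viewers (`.color`/`.polygon` commands); `--out scene.obj`
writes a mesh any 3D tool can load, and `--out scene.json` a lossless
parameter dump.

Multi-model files produce one scene per frame (`--models all --out
frame_{i}.json`), with ligand zones re-evaluated per frame or frozen to frame
0 (`--freeze-zone`).

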