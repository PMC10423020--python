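ALA:
  accent_color: null
  accent_part: none
  base_color:
  - 0.0
  - 0.8
  - 0.0
  - 1.0
  class: hydrophobic
  shape: sphere
  sizing_rule: sphere_cb
ARG:
  accent_color:
  - 0.0
  - 0.0
  - 0.35
  - 1.0
  accent_part: end_face
  base_color:
  - 0.0
  - 0.0
  - 0.55
  - 1.0
  class: positive
  shape: cuboid
  sizing_rule: cuboid
ASN:
  accent_color:
  - 0.85
  - 0.0
  - 0.0
  - 1.0
  accent_part: base_face
  base_color:
  - 0.6
  - 0.6
  - 0.6
  - 1.0
  class: neutral_polar
  shape: triangular_prism
  sizing_rule: tri_prism
ASP:
  accent_color:
  - 0.55
  - 0.0
  - 0.0
  - 1.0
  accent_part: base_face
  base_color:
  - 0.85
  - 0.0
  - 0.0
  - 1.0
  class: negative
  shape: triangular_prism
  sizing_rule: tri_prism
CYS:
  accent_color:
  - 1.0
  - 0.85
  - 0.0
  - 1.0
  accent_part: tip
  base_color:
  - 0.6
  - 0.6
  - 0.6
  - 1.0
  class: neutral_polar
  shape: pyramid
  sizing_rule: pyramid
GLN:
  accent_color:
  - 0.85
  - 0.0
  - 0.0
  - 1.0
  accent_part: base_face
  base_color:
  - 0.6
  - 0.6
  - 0.6
  - 1.0
  class: neutral_polar
  shape: triangular_prism
  sizing_rule: tri_prism
GLU:
  accent_color:
  - 0.55
  - 0.0
  - 0.0
  - 1.0
  accent_part: base_face
  base_color:
  - 0.85
  - 0.0
  - 0.0
  - 1.0
  class: negative
  shape: triangular_prism
  sizing_rule: tri_prism
GLY:
  accent_color: null
  accent_part: none
  base_color:
  - 0.0
  - 0.8
  - 0.0
  - 1.0
  class: hydrophobic
  shape: sphere
  sizing_rule: sphere_ca
HIS:
  accent_color: null
  accent_part: none
  base_color:
  - 0.3
  - 0.9
  - 0.75
  - 1.0
  class: neutral_polar
  shape: pentagonal_prism
  sizing_rule: pent_prism
ILE:
  accent_color: null
  accent_part: none
  base_color:
  - 0.0
  - 0.8
  - 0.0
  - 1.0
  class: hydrophobic
  shape: ellipsoid
  sizing_rule: ellipsoid
LEU:
  accent_color: null
  accent_part: none
  base_color:
  - 0.0
  - 0.8
  - 0.0
  - 1.0
  class: hydrophobic
  shape: ellipsoid
  sizing_rule: ellipsoid
LYS:
  accent_color:
  - 0.0
  - 0.0
  - 0.35
  - 1.0
  accent_part: end_face
  base_color:
  - 0.0
  - 0.0
  - 0.55
  - 1.0
  class: positive
  shape: cuboid
  sizing_rule: cuboid
MET:
  accent_color:
  - 1.0
  - 0.85
  - 0.0
  - 1.0
  accent_part: end_band
  base_color:
  - 0.0
  - 0.8
  - 0.0
  - 1.0
  class: hydrophobic
  shape: ellipsoid
  sizing_rule: ellipsoid
PHE:
  accent_color: null
  accent_part: none
  base_color:
  - 0.0
  - 0.8
  - 0.0
  - 1.0
  class: hydrophobic
  shape: hexagonal_prism
  sizing_rule: hex_prism
PRO:
  accent_color: null
  accent_part: none
  base_color:
  - 0.6
  - 0.6
  - 0.6
  - 1.0
  class: proline
  shape: cube
  sizing_rule: cube
SER:
  accent_color:
  - 0.85
  - 0.0
  - 0.0
  - 1.0
  accent_part: tip
  base_color:
  - 0.6
  - 0.6
  - 0.6
  - 1.0
  class: neutral_polar
  shape: pyramid
  sizing_rule: pyramid
THR:
  accent_color:
  - 0.85
  - 0.0
  - 0.0
  - 1.0
  accent_part: tip
  base_color:
  - 0.6
  - 0.6
  - 0.6
  - 1.0
  class: neutral_polar
  shape: pyramid
  sizing_rule: pyramid
TRP:
  accent_color: null
  accent_part: none
  base_color:
  - 0.0
  - 0.8
  - 0.0
  - 1.0
  class: hydrophobic
  shape: hexagonal_prism
  sizing_rule: hex_prism
TYR:
  accent_color:
  - 0.85
  - 0.0
  - 0.0
  - 1.0
  accent_part: ring_segment
  base_color:
  - 0.6
  - 0.6
  - 0.6
  - 1.0
  class: neutral_polar
  shape: hexagonal_prism
  sizing_rule: hex_prism
VAL:
  accent_color: null
  accent_part: none
  base_color:
  - 0.0
  - 0.8
  - 0.0
  - 1.0
  class: hydrophobic
  shape: ellipsoid
  sizing_rule: ellipsoid
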