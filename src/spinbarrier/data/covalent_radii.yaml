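# Single-bond covalent radii (Angstrom), Cordero-style consensus values.
# Used by infer_bonds: atoms i, j are bonded iff
#   d(i,j) <= scale * (radius_i + radius_j),   default scale 1.2
units: Angstrom
radii:
  H: 0.31
  C: 0.76
  N: 0.71
  O: 0.66
  F: 0.57
  S: 1.05
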