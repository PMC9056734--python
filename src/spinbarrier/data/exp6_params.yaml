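# Buckingham exp-6 non-bonded atom-atom parameters, E(r) = -A*r^-6 + B*exp(-C*r)
#
# units:
#   A: kJ mol^-1 Angstrom^6
#   B: kJ mol^-1
#   C: Angstrom^-1
#
# Provenance: representative Williams-type exp-6 values assembled for
# qualitative torsion-landscape work (3-fold methyl minima, barrier
# asymmetry). This table is a documented stand-in, NOT a reproduction of
# any specific historical parameterisation; pass your own table to every
# operation for quantitative work.
units:
  A: kJ/mol*A^6
  B: kJ/mol
  C: 1/A
parameters:
  H: {A: 136.4,  B: 11677.0,  C: 3.74}
  C: {A: 2439.8, B: 369743.0, C: 3.60}
  N: {A: 1378.4, B: 254529.0, C: 3.78}
  O: {A: 1123.6, B: 230064.0, C: 3.96}
  F: {A: 586.7,  B: 150226.0, C: 4.22}
  S: {A: 7000.0, B: 556000.0, C: 3.49}
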