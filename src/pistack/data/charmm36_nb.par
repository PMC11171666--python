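# CHARMM36-style nonbonded parameters.
# Columns: type  epsilon(kcal/mol, tabulated as negative well depth)  Rmin/2(A)  default_charge(e)
# Aromatic C-H convention: CA -0.115 e / HA +0.115 e; ring-fusion CA carry 0 e
# (assigned by the builders).  H/OH1 are the TIP3P water hydrogen/oxygen.
C    -0.110  2.0000   0.000
CA   -0.070  1.9924  -0.115
CC   -0.070  2.0000   0.000
CE1  -0.068  2.0900   0.000
CE2  -0.064  2.0800   0.000
C3   -0.020  2.2750   0.000
H    -0.046  0.2245   0.417
HA   -0.022  1.3200   0.115
OB   -0.120  1.7000   0.000
OH1  -0.152  1.7700  -0.834
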