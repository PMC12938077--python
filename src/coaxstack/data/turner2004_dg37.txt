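# Turner 2004 nearest-neighbor free-energy parameters (dG at 37 C, kcal/mol).
# Source: NNDB Turner 2004 rule set (https://rna.urmc.rochester.edu/NNDB/turner04/).
# Step notation XY/WZ: top strand 5'-X Y-3' over bottom strand 3'-W Z-5',
# with X.W and Y.Z the two base pairs of the step.
# STACK: helix nearest-neighbor stacks. Watson-Crick x Watson-Crick entries carry
#   the published 0.01 kcal/mol precision (Xia et al. 1998); entries involving GU
#   wobble pairs are tabulated at 0.1 kcal/mol precision.
# FLUSH_COAX: coaxial stacking free energy with zero intervening nucleotides.
#   Convention: a flush stack across a junction nick is assigned the free energy of
#   the corresponding continuous-backbone helix stack (Walter & Turner).
# MISMATCH_COAX: base contribution for a mismatch-mediated coaxial stack (one
#   intervening nucleotide); approximated here by the interface-step helix stack,
#   to which the separate terminal-mismatch penalty (MISMATCH_PENALTY) is added
#   by the energy function. Substitute measured stack(1) values here if available.
VERSION turner2004
INIT 4.09
AU_END 0.45
SYM 0.43
MISMATCH_PENALTY 2.1
COAX_A 9.3
COAX_B 0.0
COAX_C -0.6
STACK AA/UU -0.93
STACK AC/UG -2.24
STACK AG/UC -2.08
STACK AG/UU -0.60
STACK AU/UA -1.10
STACK AU/UG -1.40
STACK CA/GU -2.11
STACK CC/GG -3.26
STACK CG/GC -2.36
STACK CG/GU -1.40
STACK CU/GA -2.08
STACK CU/GG -2.10
STACK GA/CU -2.35
STACK GA/UU -1.30
STACK GC/CG -3.42
STACK GC/UG -2.50
STACK GG/CC -3.26
STACK GG/CU -1.50
STACK GG/UC -2.10
STACK GG/UU -0.50
STACK GU/CA -2.24
STACK GU/CG -2.50
STACK GU/UA -1.40
STACK GU/UG 1.30
STACK UA/AU -1.33
STACK UA/GU -1.00
STACK UC/AG -2.35
STACK UC/GG -1.50
STACK UG/AC -2.11
STACK UG/AU -1.00
STACK UG/GC -1.40
STACK UG/GU 0.30
STACK UU/AA -0.93
STACK UU/AG -1.30
STACK UU/GA -0.60
STACK UU/GG -0.50
FLUSH_COAX AA/UU -0.93
FLUSH_COAX AC/UG -2.24
FLUSH_COAX AG/UC -2.08
FLUSH_COAX AG/UU -0.60
FLUSH_COAX AU/UA -1.10
FLUSH_COAX AU/UG -1.40
FLUSH_COAX CA/GU -2.11
FLUSH_COAX CC/GG -3.26
FLUSH_COAX CG/GC -2.36
FLUSH_COAX CG/GU -1.40
FLUSH_COAX CU/GA -2.08
FLUSH_COAX CU/GG -2.10
FLUSH_COAX GA/CU -2.35
FLUSH_COAX GA/UU -1.30
FLUSH_COAX GC/CG -3.42
FLUSH_COAX GC/UG -2.50
FLUSH_COAX GG/CC -3.26
FLUSH_COAX GG/CU -1.50
FLUSH_COAX GG/UC -2.10
FLUSH_COAX GG/UU -0.50
FLUSH_COAX GU/CA -2.24
FLUSH_COAX GU/CG -2.50
FLUSH_COAX GU/UA -1.40
FLUSH_COAX GU/UG 1.30
FLUSH_COAX UA/AU -1.33
FLUSH_COAX UA/GU -1.00
FLUSH_COAX UC/AG -2.35
FLUSH_COAX UC/GG -1.50
FLUSH_COAX UG/AC -2.11
FLUSH_COAX UG/AU -1.00
FLUSH_COAX UG/GC -1.40
FLUSH_COAX UG/GU 0.30
FLUSH_COAX UU/AA -0.93
FLUSH_COAX UU/AG -1.30
FLUSH_COAX UU/GA -0.60
FLUSH_COAX UU/GG -0.50
MISMATCH_COAX AA/UU -0.93
MISMATCH_COAX AC/UG -2.24
MISMATCH_COAX AG/UC -2.08
MISMATCH_COAX AG/UU -0.60
MISMATCH_COAX AU/UA -1.10
MISMATCH_COAX AU/UG -1.40
MISMATCH_COAX CA/GU -2.11
MISMATCH_COAX CC/GG -3.26
MISMATCH_COAX CG/GC -2.36
MISMATCH_COAX CG/GU -1.40
MISMATCH_COAX CU/GA -2.08
MISMATCH_COAX CU/GG -2.10
MISMATCH_COAX GA/CU -2.35
MISMATCH_COAX GA/UU -1.30
MISMATCH_COAX GC/CG -3.42
MISMATCH_COAX GC/UG -2.50
MISMATCH_COAX GG/CC -3.26
MISMATCH_COAX GG/CU -1.50
MISMATCH_COAX GG/UC -2.10
MISMATCH_COAX GG/UU -0.50
MISMATCH_COAX GU/CA -2.24
MISMATCH_COAX GU/CG -2.50
MISMATCH_COAX GU/UA -1.40
MISMATCH_COAX GU/UG 1.30
MISMATCH_COAX UA/AU -1.33
MISMATCH_COAX UA/GU -1.00
MISMATCH_COAX UC/AG -2.35
MISMATCH_COAX UC/GG -1.50
MISMATCH_COAX UG/AC -2.11
MISMATCH_COAX UG/AU -1.00
MISMATCH_COAX UG/GC -1.40
MISMATCH_COAX UG/GU 0.30
MISMATCH_COAX UU/AA -0.93
MISMATCH_COAX UU/AG -1.30
MISMATCH_COAX UU/GA -0.60
MISMATCH_COAX UU/GG -0.50
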