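HETATM    1 C1  RIB A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2 C2  RIB A   1       1.530   0.000   0.000  1.00  0.00           C
HETATM    3 C3  RIB A   1       2.103   1.419   0.000  1.00  0.00           C
HETATM    4 C4  RIB A   1       1.700   2.199   1.253  1.00  0.00           C
HETATM    5 C5  RIB A   1       2.428   3.542   1.350  1.00  0.00           C
HETATM    6 O1  RIB A   1      -0.477  -1.331   0.211  1.00  0.00           O
HETATM    7 O2  RIB A   1       1.976  -0.695  -1.167  1.00  0.00           O
HETATM    8 O3  RIB A   1       1.617   2.096  -1.162  1.00  0.00           O
HETATM    9 O4  RIB A   1       2.021   1.433   2.416  1.00  0.00           O
HETATM   10 O5  RIB A   1       3.807   3.316   1.655  1.00  0.00           O
HETATM   11 H11 RIB A   1      -0.364   0.647   0.799  1.00  0.00           H
HETATM   12 H12 RIB A   1      -0.364   0.368  -0.959  1.00  0.00           H
HETATM   13 H2  RIB A   1       1.870  -0.530   0.890  1.00  0.00           H
HETATM   14 H3  RIB A   1       3.190   1.346  -0.050  1.00  0.00           H
HETATM   15 H4  RIB A   1       0.628   2.395   1.230  1.00  0.00           H
HETATM   16 H51 RIB A   1       2.349   4.069   0.399  1.00  0.00           H
HETATM   17 H52 RIB A   1       1.976   4.145   2.137  1.00  0.00           H
HETATM   18 HO1 RIB A   1      -1.447  -1.331   0.211  1.00  0.00           H
HETATM   19 HO2 RIB A   1       1.613  -1.594  -1.167  1.00  0.00           H
HETATM   20 HO3 RIB A   1       1.872   1.601  -1.956  1.00  0.00           H
HETATM   21 HO4 RIB A   1       1.765   1.928   3.211  1.00  0.00           H
HETATM   22 HO5 RIB A   1       4.268   4.167   1.717  1.00  0.00           H
HETATM   23 O   HOH A   2       9.000   9.000   9.000  1.00  0.00           O
HETATM   24 O   HOH A   3      11.000   9.000   9.000  1.00  0.00           O
END
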