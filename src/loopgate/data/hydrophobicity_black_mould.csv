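residue,hydrophobicity
ALA,0.115
ARG,-0.501
ASN,-0.265
ASP,-0.473
CYS,0.179
GLN,-0.250
GLU,-0.458
GLY,0.000
HIS,-0.336
ILE,0.442
LEU,0.442
LYS,-0.218
MET,0.237
PHE,0.499
PRO,0.210
SER,-0.142
THR,-0.051
TRP,0.377
TYR,0.379
VAL,0.324
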