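residue,atom,sasa_A2
ALA,CB,56.9850
ARG,CB,19.3724
ARG,CD,28.1780
ARG,CG,17.9886
ARG,CZ,11.1957
ARG,NE,12.6446
ARG,NH1,56.9577
ARG,NH2,49.2115
ASN,CB,28.5554
ASN,CG,6.6671
ASN,ND2,54.9073
ASN,OD1,23.7730
ASP,CB,29.1843
ASP,CG,7.0445
ASP,OD1,23.8846
ASP,OD2,53.0149
CYS,CB,31.5744
CYS,SG,62.4632
GLN,CB,19.7498
GLN,CD,9.6862
GLN,CG,14.3406
GLN,NE2,55.0212
GLN,OE1,42.5235
GLU,CB,19.8755
GLU,CD,10.0636
GLU,CG,14.5922
GLU,OE1,42.6351
GLU,OE2,52.9033
GLY,CA,26.6685
HIS,CB,27.6748
HIS,CD2,26.6685
HIS,CE1,45.4119
HIS,CG,3.1449
HIS,ND1,15.0368
HIS,NE2,27.6815
ILE,CB,9.5604
ILE,CD1,61.8909
ILE,CG1,16.2275
ILE,CG2,40.5059
LEU,CB,24.4042
LEU,CD1,61.8909
LEU,CD2,36.1031
LEU,CG,4.7802
LYS,CB,25.1589
LYS,CD,27.9264
LYS,CE,37.1094
LYS,CG,10.8183
LYS,NZ,56.9577
MET,CB,24.0268
MET,CE,67.9291
MET,CG,10.5667
MET,SD,46.6464
PHE,CB,27.6748
PHE,CD1,17.1081
PHE,CD2,16.9823
PHE,CE1,32.2034
PHE,CE2,35.4741
PHE,CG,2.8933
PHE,CZ,34.9709
PRO,CB,32.2034
PRO,CD,7.6735
PRO,CG,41.0090
SER,CB,34.8451
SER,OG,40.9610
THR,CB,13.3342
THR,CG2,48.1793
THR,OG1,36.4966
TRP,CB,27.5490
TRP,CD1,23.9010
TRP,CD2,3.0191
TRP,CE2,6.2897
TRP,CE3,13.0826
TRP,CG,2.8933
TRP,CH2,34.9709
TRP,CZ2,33.8387
TRP,CZ3,29.6875
TRP,NE1,25.7449
TYR,CB,27.6748
TYR,CD1,17.1081
TYR,CD2,17.1081
TYR,CE1,28.5554
TYR,CE2,31.9518
TYR,CG,2.8933
TYR,CZ,7.1703
TYR,OH,51.7872
VAL,CB,10.4410
VAL,CG1,47.4246
VAL,CG2,47.5504
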