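set,element,radius
bondi,H,1.20
bondi,C,1.70
bondi,N,1.55
bondi,O,1.52
bondi,F,1.47
bondi,P,1.80
bondi,S,1.80
bondi,Cl,1.75
bondi,Br,1.85
bondi,I,1.98
bondi,Se,1.90
bondi,Na,2.27
bondi,K,2.75
bondi,Mg,1.73
bondi,Zn,1.39
bondi,*,1.70
chothia,H,1.00
chothia,C,1.87
chothia,N,1.65
chothia,O,1.40
chothia,S,1.85
chothia,P,1.90
chothia,*,1.80
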