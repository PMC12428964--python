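cell_line,species,subtype,mycn,alk,profile,profile_partial
NBL-S,Human,Adr,No,No,E,0
LS,Human,Mes,Yes,No,E,1
CHP-134,Human,Adr,Yes,No,B,0
SH-SY5Y,Human,Adr,No,F1174L,E,0
SK-N-AS,Human,Mes,No,No,C,0
SK-N-BE(2)-C,Human,Adr,Yes,No,E,0
GI-ME-N,Human,Mes,No,No,C,0
LA-N-5,Human,Adr,Yes,R1275Q,A,1
ACN,Human,Mes,No,No,C,0
IMR-32,Human,Adr,Yes,No,E,1
NXS2,Murine,unknown,unknown,unknown,E,0
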