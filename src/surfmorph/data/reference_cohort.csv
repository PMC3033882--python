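patient,hemisphere,thickness_detected,thickness_extra_mm2,gwc_detected,gwc_extra_mm2,union_detected,union_extra_mm2
1,L,no,942,yes,312,yes,1255
1,R,yes,0,yes,0,yes,0
2,L,yes,106,no,0,yes,106
3,L,yes,507,no,146,yes,507
4,R,yes,113,no,0,yes,113
5,L,no,0,no,0,no,0
6,R,yes,408,yes,184,yes,592
7,R,yes,0,yes,45,yes,45
8,L,yes,905,yes,262,yes,1161
9,R,yes,0,yes,77,yes,77
10,R,yes,392,yes,1053,yes,1230
11,L,yes,105,no,0,yes,105
11,R,yes,486,no,0,yes,486
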