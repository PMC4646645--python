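code,group,set,kind,cat_min,cat_max,mean,sd
DisM,TOPO,topological,continuous,,,51181.13,18354.64
SOSh,TOPO,topological,continuous,,,2.55,3.34
SOSt,TOPO,topological,continuous,,,1.38,0.59
ChDe,PROFILE,measured,continuous,,,0.45,0.38
ChWi,PROFILE,measured,continuous,,,3.98,4.53
ChWV,PROFILE,measured,ordinal,1,5,1.73,0.68
CSFo,PROFILE,measured,ordinal,1,8,5.12,1.99
FlVe,PROFILE,measured,ordinal,1,5,2.81,0.87
BAEr,BED,measured,count_rate,,,0.11,0.32
BAOt,BED,measured,count_rate,,,0.09,0.36
BAWa,BED,measured,count_rate,,,0.12,0.41
CBFO,BED,measured,count_rate,,,0.06,0.53
CBFR,BED,measured,count_rate,,,0.06,0.31
InVe,BED,measured,ordinal,1,4,1.82,0.96
SMaS,BED,measured,count_rate,,,0.74,0.9
SuDi,BED,measured,ordinal,1,5,0.85,0.33
SuHa,BED,measured,continuous,,,14.68,22.45
SuMa,BED,measured,continuous,,,4.17,7.45
SuSa,BED,measured,continuous,,,57.74,25.88
SuSo,BED,measured,continuous,,,21.29,23.2
SuWo,BED,measured,continuous,,,2.12,8.08
BFLW,BANK,measured,count_rate,,,0.06,0.32
BFOt,BANK,measured,count_rate,,,0.04,0.23
BPGr,BANK,measured,ordinal,0,2,0.02,0.17
BPWa,BANK,measured,ordinal,0,2,0.01,0.11
BPno,BANK,measured,ordinal,0,2,1.45,0.87
BPRi,BANK,measured,ordinal,0,2,0.03,0.22
BPWo,BANK,measured,ordinal,0,2,0.44,0.8
RVRe,BANK,measured,ordinal,0,2,0.03,0.18
RVSp,BANK,measured,ordinal,0,2,1.73,0.56
RVTF,BANK,measured,ordinal,0,2,0.24,0.54
CFIB,LONG,measured,count_rate,,,0.02,0.16
CFLW,LONG,measured,count_rate,,,0.02,0.22
CFNa,LONG,measured,count_rate,,,0.09,0.36
CFWi,LONG,measured,count_rate,,,0.09,0.45
ChDV,LONG,measured,ordinal,1,5,1.61,0.66
FlDi,LONG,measured,ordinal,1,5,1.77,0.61
Plan,LONG,measured,ordinal,1,7,5.65,1.36
FE-CSD,PROFILE,assessed,score,1,5,4.48,0.97
FE-CSF,PROFILE,assessed,score,1,5,3.89,1.22
FE-CSW,PROFILE,assessed,score,1,5,3.44,1.1
FE-BeF,BED,assessed,score,1,5,2.02,0.16
FE-Sub,BED,assessed,score,1,5,4.21,0.66
FE-BaP,BANK,assessed,score,1,5,2.34,0.74
FE-BFe,BANK,assessed,score,1,5,4.79,0.64
FE-RVe,BANK,assessed,score,1,5,3.63,0.63
FE-ChD,LONG,assessed,score,1,5,3.66,0.72
FE-LPr,LONG,assessed,score,1,5,4.48,0.49
FE-Pla,LONG,assessed,score,1,5,4.57,0.62
FE-FPl,FLOODPLAIN,assessed,score,1,5,3.1,0.57
FE-RBS,FLOODPLAIN,assessed,score,1,5,4.09,1.19
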