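person,workplace,education,experience,sex
P1,GRA,PhD,15,M
P2,FPE,MMS,18,M
P3,TTI,MA,19,F
P4,FPE,PhD,11,F
P5,GRA,MA,14,F
P6,TTI,MA,11,M
P7,GRA,BA,8,F
P8,FPE,MA,15,M
P9,CO,PhD,17,M
P10,TTI,BA,5,F
P11,GRA,MS,16,F
P12,FPE,MMS,11,F
P13,CO,MS,9,M
P14,GRA,BA,14,M
P15,CO,MS,13,F
P16,TTI,MA,10,M
P17,GRA,PhD,9,M
P18,FPE,MS,6,F
P19,GRA,MA,11,F
P20,CO,BA,13,F
P21,CO,MMS,12,M
P22,FPE,MS,5,M
P23,GRA,MS,9,M
P24,TTI,BA,7,F
P25,CO,MMS,17,F
P26,FPE,MA,15,F
P27,CO,MA,5,F
P28,GRA,MS,14,F
P29,CO,PhD,18,M
P30,GRA,MA,11,M
P31,TTI,MS,14,F
P32,GRA,MMS,13,F
P33,GRA,PhD,7,F
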