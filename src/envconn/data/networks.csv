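seed,x,y,z,network
lANG,-57,-63,17,DMN
rANG,56,-63,18,DMN
PCC,5,-58,29,DMN
MPFC,-5,35,-9,DMN
lIPS,-27,-61,50,DAN
rIPS,26,-60,48,DAN
lFEF,-30,-9,52,DAN
rFEF,30,-9,55,DAN
rTPJ,60,-43,16,VAN
rIFG,42,5,1,VAN
lTPJ,-54,-33,-4,LANG
lIFG,-47,14,1,LANG
lSMA,-1,-17,55,MOT
lCS,-45,-17,49,MOT
rCS,45,-17,49,MOT
lS2,-42,-13,10,MOT
rS2,42,-13,10,MOT
lV1V2,-27,-81,-13,VIS
rV1V2,27,-81,-13,VIS
lMT,-45,-81,4,VIS
rMT,45,-81,4,VIS
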