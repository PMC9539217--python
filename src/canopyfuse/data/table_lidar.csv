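predicted,JM,LG,TA,QM,UP
JM,37,3,4,2,2
LG,3,132,6,0,3
TA,10,9,66,8,10
QM,1,0,7,17,4
UP,2,1,6,2,17
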