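predicted,JM,LG,TA,QM,UP
JM,42,4,2,1,2
LG,0,139,3,0,2
TA,6,1,77,6,5
QM,3,0,3,21,3
UP,2,1,4,1,24
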