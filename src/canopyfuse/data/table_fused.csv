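predicted,JM,LG,TA,QM,UP
JM,43,2,2,0,1
LG,0,143,2,0,2
TA,5,0,78,4,4
QM,2,0,3,24,3
UP,3,0,4,1,26
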