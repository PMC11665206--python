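,LAD,LCX,RCA
LAD,18,1,1
LCX,0,4,2
RCA,2,0,5
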