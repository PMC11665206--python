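score_group,seg01,seg02,seg03,seg04,seg05,seg06,seg07,seg08,seg09,seg10,seg11,seg12,seg13,seg14,seg15,seg16,seg17
normal,24,22,20,22,24,27,16,16,17,18,22,20,13,13,16,17,13
hypokinesis,8,9,12,10,7,6,17,16,16,15,10,13,19,18,17,15,19
akinesis,1,2,1,1,2,0,0,1,0,0,1,0,1,2,0,1,1
dyskinesis,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
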