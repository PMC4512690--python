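,A1,A2,A3,A4,A5,A6,A7,A8,A9,A10,A11,A12
A1,592,3,0,0,0,0,0,0,0,1,1,0
A2,1,515,4,0,0,0,0,0,2,2,7,0
A3,1,4,521,0,0,0,0,1,0,0,2,0
A4,1,0,2,710,0,0,0,0,2,0,0,0
A5,0,0,2,2,270,0,0,2,0,1,0,0
A6,0,0,0,0,0,471,0,0,0,1,0,0
A7,0,0,1,2,0,0,551,0,0,1,4,0
A8,0,1,4,2,0,0,0,304,3,1,2,0
A9,0,1,12,8,0,0,0,4,288,0,4,0
A10,0,2,2,1,0,0,2,0,0,469,2,0
A11,0,0,1,1,0,0,0,0,1,1,661,0
A12,0,2,0,2,0,0,0,1,2,0,3,132
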