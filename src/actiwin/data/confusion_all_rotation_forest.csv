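,A1,A2,A3,A4,A5,A6,A7,A8,A9,A10,A11,A12
A1,591,1,1,0,0,0,0,0,0,2,2,0
A2,0,516,3,0,0,0,0,0,0,3,9,0
A3,0,7,515,0,0,0,0,0,1,0,6,0
A4,0,0,0,707,0,0,0,2,5,0,1,0
A5,0,1,2,1,266,0,1,3,1,1,1,0
A6,0,0,0,0,0,471,0,0,0,1,0,0
A7,0,2,1,1,0,0,551,0,0,1,3,0
A8,0,1,8,0,0,0,1,303,0,0,4,0
A9,0,2,9,2,0,0,1,8,287,3,5,0
A10,0,1,2,2,0,1,0,1,0,466,5,0
A11,0,1,6,0,0,0,0,0,0,5,653,0
A12,0,1,0,0,0,2,0,2,1,0,3,133
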