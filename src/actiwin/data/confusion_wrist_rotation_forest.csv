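,A1,A2,A3,A4,A5,A6,A7,A8,A9,A10,A11,A12
A1,561,8,6,0,0,1,1,1,0,7,12,0
A2,6,475,24,0,0,0,1,2,1,4,18,0
A3,4,17,489,0,0,1,0,1,2,1,14,0
A4,0,1,2,682,0,0,0,15,3,0,8,4
A5,2,0,3,1,265,0,3,2,0,0,1,0
A6,1,0,0,0,0,464,0,0,2,0,5,0
A7,0,2,0,3,0,0,546,0,0,3,4,1
A8,1,2,10,3,1,1,0,284,4,0,11,0
A9,0,1,18,3,0,1,0,7,270,0,17,0
A10,0,0,6,0,0,1,0,1,1,449,20,0
A11,1,7,12,0,0,1,1,0,0,3,640,0
A12,0,2,2,1,0,0,0,0,0,0,7,130
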