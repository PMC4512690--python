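,A1,A2,A3,A4,A5,A6,A7,A8,A9,A10,A11,A12
A1,572,1,12,0,0,5,0,1,0,1,5,0
A2,1,469,27,0,0,0,0,1,1,12,20,0
A3,1,8,435,0,0,0,0,0,1,10,74,0
A4,0,0,1,685,0,3,18,2,3,2,1,0
A5,0,0,1,0,265,2,0,3,0,2,4,0
A6,0,0,0,0,0,463,0,0,1,4,4,0
A7,0,1,0,18,0,2,529,0,2,1,6,0
A8,0,1,5,2,0,2,2,291,0,4,10,0
A9,0,1,7,2,3,6,0,5,277,7,9,0
A10,0,1,1,1,0,5,1,3,0,440,26,0
A11,1,4,29,0,0,0,0,0,1,32,598,0
A12,0,1,1,0,2,0,0,0,1,1,3,133
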