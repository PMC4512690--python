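,A1,A2,A3,A4,A5,A6,A7,A8,A9,A10,A11,A12
A1,583,6,7,0,0,0,0,0,0,1,0,0
A2,3,474,35,0,0,1,0,1,0,4,13,0
A3,1,23,492,0,0,0,0,1,0,0,12,0
A4,0,0,4,691,0,6,10,1,0,2,1,0
A5,0,1,1,0,265,0,1,2,2,2,2,1
A6,2,0,0,0,0,459,0,0,0,9,2,0
A7,0,1,0,26,0,1,517,3,3,1,7,0
A8,0,4,9,2,0,5,1,294,1,0,1,0
A9,1,1,16,5,1,0,2,7,280,0,4,0
A10,1,0,2,2,0,5,0,3,0,441,24,0
A11,1,5,20,0,0,0,0,0,0,15,624,0
A12,0,2,1,0,0,2,0,0,1,0,2,134
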