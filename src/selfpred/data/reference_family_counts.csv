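family,n_selfed,n_crossed
GEN1,12,16
GEN2,3,1
GEN3,19,0
GEN4,9,24
GEN5,29,4
GEN6,1,0
GEN7,13,20
GEN8,10,9
GEN9,2,1
GEN10,14,0
GEN11,28,3
GEN12,6,21
GEN13,1,32
GEN14,15,1
GEN15,2,1
GEN16,13,18
GEN17,1,0
GEN18,0,3
GEN19,27,3
GEN20,8,21
GEN21,3,0
GEN22,8,12
GEN23,17,0
GEN24,1,0
GEN25,32,0
GEN26,26,3
GEN27,15,2
GEN28,11,2
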