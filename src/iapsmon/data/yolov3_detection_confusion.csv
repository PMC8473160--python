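observed,Cytisus scoparius,Lupinus polyphyllus,Pastinaca sativa,Reynoutria,Rosa rugosa,Solidago,No species
Cytisus scoparius,76,0,0,0,0,0,150
Lupinus polyphyllus,0,6,0,0,0,0,121
Pastinaca sativa,0,0,25,0,0,1,170
Reynoutria,0,0,0,56,3,0,69
Rosa rugosa,0,0,0,0,130,0,157
Solidago,4,0,0,0,0,156,584
No species,13,2,28,14,19,57,0
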