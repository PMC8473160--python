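observed,Cytisus scoparius,Lupinus polyphyllus,Pastinaca sativa,Reynoutria,Rosa rugosa,Solidago,No species
Cytisus scoparius,54,2,0,0,0,2,103
Lupinus polyphyllus,0,2,4,0,0,4,56
Pastinaca sativa,0,1,5,0,0,11,107
Reynoutria,0,0,0,91,0,1,26
Rosa rugosa,2,4,6,0,115,13,85
Solidago,0,4,2,0,0,248,197
No species,11,9,73,51,2,95,754
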