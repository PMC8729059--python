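,NILM,ASC-US,LSIL,ASC-H,HSIL,SCC
NILM,49,13,5,1,15,17
ASC-US,0,19,0,1,2,0
LSIL,0,16,9,0,1,0
ASC-H,0,18,0,9,2,0
HSIL,0,2,0,1,23,0
SCC,0,0,0,0,1,18
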