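,NILM,ASC-US,LSIL,ASC-H,HSIL,SCC
NILM,24,1,0,0,0,1
ASC-US,0,12,4,6,4,3
LSIL,2,4,16,3,1,1
ASC-H,0,1,0,28,2,0
HSIL,0,2,1,3,22,8
SCC,0,0,0,2,9,45
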