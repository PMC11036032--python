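patch,A,B,C,D
patch_1,0,0,0,-1
patch_2,0,0,0,1
patch_3,1,-1,1,1
patch_4,0,1,0,1
patch_5,1,1,-1,0
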