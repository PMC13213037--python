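criterion,DM1,DM2,DM3
C12,-,-,-
C11,MDL,MDL,WL
C10,MDL,L,MDL
C9,L,RL,MDL
C8,WL,MDL,MDL
C7,WL,MDL,MDM
C6,MDL,L,L
C5,WL,WL,MDM
C4,L,WL,MDM
C3,L,MDL,MDM
C2,MDL,MDL,WL
C1,MDL,WL,MDL
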