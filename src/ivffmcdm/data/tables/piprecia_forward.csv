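criterion,DM1,DM2,DM3
C1,-,-,-
C2,M,SM,MDM
C3,MDM,M,SM
C4,SM,MDM,M
C5,MM,SM,MDM
C6,SM,MDM,M
C7,MDM,M,SM
C8,SM,SM,SM
C9,MM,MM,M
C10,SM,M,MDM
C11,M,M,SM
C12,SM,SM,SM
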