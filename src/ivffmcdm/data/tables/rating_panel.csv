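alternative,dm,C1,C2,C3,C4,C5,C6,C7,C8,C9,C10,C11,C12
EAM1,DM1,MH,MH,H,H,ML,VH,L,M,MH,M,H,L
EAM1,DM2,MH,H,H,VH,MH,MH,ML,M,H,H,H,L
EAM1,DM3,H,VH,H,H,VH,ML,H,L,MH,VH,H,ML
EAM2,DM1,ML,VH,H,MH,MH,M,VH,L,MH,MH,MH,L
EAM2,DM2,MH,VH,H,MH,H,ML,VH,ML,MH,H,H,ML
EAM2,DM3,MH,VH,H,VH,ML,H,L,H,VH,H,M,L
EAM3,DM1,MH,VH,VH,H,VH,ML,VH,L,MH,MH,MH,ML
EAM3,DM2,H,VH,VH,H,VH,ML,VH,ML,H,MH,H,ML
EAM3,DM3,MH,VH,VH,H,H,ML,VH,L,H,MH,MH,ML
EAM4,DM1,MH,MH,MH,H,ML,MH,L,M,MH,MH,M,L
EAM4,DM2,MH,H,H,MH,MH,ML,H,ML,M,MH,MH,ML
EAM4,DM3,M,MH,MH,MH,MH,ML,H,L,MH,H,H,ML
EAM5,DM1,MH,H,H,H,MH,M,MH,ML,MH,H,MH,ML
EAM5,DM2,H,VH,VH,H,H,MH,ML,MH,VH,M,H,L
EAM5,DM3,MH,VH,H,H,H,ML,H,L,MH,VH,H,ML
EAM6,DM1,ML,M,MH,MH,H,ML,MH,ML,MH,M,MH,ML
EAM6,DM2,M,MH,M,M,MH,L,H,ML,M,MH,MH,ML
EAM6,DM3,ML,MH,M,MH,MH,L,H,ML,M,MH,MH,L
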