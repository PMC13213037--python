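alternative,Q
EAM1,0.101
EAM2,0.086
EAM3,0.096
EAM4,0.082
EAM5,0.116
EAM6,0.072
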