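alternative,if_q,if_rank,pf_q,pf_rank,ivff_q,ivff_rank
EAM1,0.1107,6,0.1144,6,0.1011,5
EAM2,0.0705,3,0.0730,3,0.0865,3
EAM3,0.0987,4,0.0976,4,0.0957,4
EAM4,0.0506,1,0.0514,1,0.0821,2
EAM5,0.1018,5,0.1050,5,0.1160,6
EAM6,0.0589,2,0.0596,2,0.0722,1
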