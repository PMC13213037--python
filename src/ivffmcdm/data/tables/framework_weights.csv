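criterion,if_w,pf_w,ivff_w,mean,std,rank_range
C1,0.210,0.207,0.219,0.212,0.0063,1-2
C12,0.272,0.277,0.148,0.232,0.0742,1-2
C2,0.122,0.121,0.125,0.123,0.0021,3-4
C11,0.126,0.126,0.115,0.122,0.0063,3-4
C3,0.071,0.071,0.072,0.071,0.0006,5-6
C10,0.058,0.057,0.084,0.066,0.0153,5-6
C4,0.042,0.042,0.044,0.043,0.0012,7-9
C9,0.027,0.026,0.056,0.036,0.0171,7-8
C5,0.025,0.026,0.032,0.028,0.0038,9-10
C8,0.016,0.015,0.046,0.026,0.0175,8-11
C6,0.016,0.017,0.029,0.021,0.0073,10-12
C7,0.014,0.014,0.031,0.020,0.0098,11-12
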