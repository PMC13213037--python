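method,O1,O2,O3,O4,O5,O6,O7,O8,O9,O10,O11,O12,O13,O14,O15,O16,O17,O18,O19,O20,O21,O22,O23
EAM1,6,4,5,5,4,6,4,7,5,5,6,4,7,6,6,6,4,5,5,4,5,6,5
EAM2,5,4,4,6,4,5,4,6,5,6,5,4,6,5,5,5,4,5,6,5,5,6,5
EAM3,69.14,70.37,72.22,70.37,71.60,72.22,70.37,65.43,70.37,77.16,65.43,77.16,76.54,70.37,70.37,71.60,70.37,72.22,70.37,76.54,70.37,74.69,65.43
EAM4,2,3,3,3,3,2,2,4,3,3,4,3,4,3,3,4,3,3,3,3,2.0,3,2
EAM5,10,9,8,12,10,8,9,11,10,13,12,9,12,10,10,12,9,10,12,11,10,12,9
EAM6,10,9,10,10,9,9,9,10,9,10,10,9,10,10,9,10,9,10,10,10,9,10,9
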