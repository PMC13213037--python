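operation,e,d,w
O1,0.6197,0.3803,0.0207
O2,0.1786,0.8214,0.0447
O3,0.1785,0.8215,0.0447
O4,0.1846,0.8154,0.0444
O5,0.1792,0.8208,0.0447
O6,0.1790,0.8210,0.0447
O7,0.1775,0.8225,0.0448
O8,0.1884,0.8116,0.0442
O9,0.1818,0.8182,0.0445
O10,0.1831,0.8169,0.0445
O11,0.1875,0.8125,0.0442
O12,0.1763,0.8237,0.0448
O13,0.1852,0.8148,0.0443
O14,0.1831,0.8169,0.0444
O15,0.1828,0.8172,0.0445
O16,0.1853,0.8147,0.0443
O17,0.1786,0.8214,0.0447
O18,0.1814,0.8186,0.0445
O19,0.1846,0.8154,0.0444
O20,0.1797,0.8203,0.0446
O21,0.1818,0.8182,0.0445
O22,0.1841,0.8159,0.0444
O23,0.1815,0.8185,0.0445
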