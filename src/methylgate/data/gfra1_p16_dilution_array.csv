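meth_dilution,te_dilution,total_ng,net_ng,meth_pct,COL2A1_ct,COL2A1_detection,GFRA1_ct,GFRA1_detection,P16_ct,P16_detection
1,1,18.78,1.18,6.3,27.90,FULL,32.82,FULL,33.58,FULL
1/2,1,18.78,0.59,3.1,28.18,FULL,33.92,FULL,35.04,FULL
1/4,1,18.78,0.29,1.6,27.93,FULL,34.78,FULL,35.13,FULL
1/8,1,18.78,0.15,0.8,28.18,FULL,35.84,FULL,36.61,FULL
1/16,1,18.78,0.07,0.4,28.09,FULL,37.38,PARTIAL,37.76,FULL
1/32,1,18.78,0.04,0.2,28.05,FULL,38.25,PARTIAL,38.49,PARTIAL
1/64,1,18.78,0.02,0.1,28.10,FULL,38.99,PARTIAL,38.87,PARTIAL
1,1/2,9.39,0.59,6.3,29.34,FULL,34.16,FULL,34.70,FULL
1/2,1/2,9.39,0.29,3.1,29.35,FULL,35.35,FULL,36.21,FULL
1/4,1/2,9.39,0.15,1.6,29.33,FULL,36.15,FULL,37.30,FULL
1/8,1/2,9.39,0.07,0.8,29.41,FULL,37.41,PARTIAL,38.07,FULL
1/16,1/2,9.39,0.04,0.4,29.53,FULL,39.84,PARTIAL,38.63,FULL
1/32,1/2,9.39,0.02,0.2,29.38,FULL,37.95,PARTIAL,38.74,PARTIAL
1/64,1/2,9.39,0.01,0.1,29.26,FULL,36.83,PARTIAL,,NONE
1,1/4,4.70,0.29,6.3,30.73,FULL,35.28,FULL,36.78,FULL
1/2,1/4,4.70,0.15,3.1,31.08,FULL,37.59,FULL,37.73,FULL
1/4,1/4,4.70,0.07,1.6,31.10,FULL,39.17,PARTIAL,38.18,PARTIAL
1/8,1/4,4.70,0.04,0.8,30.64,FULL,38.12,PARTIAL,37.71,PARTIAL
1/16,1/4,4.70,0.02,0.4,30.95,FULL,39.74,PARTIAL,,NONE
1/32,1/4,4.70,0.01,0.2,30.78,FULL,,NONE,,NONE
1/64,1/4,4.70,0.005,0.1,30.83,FULL,37.96,PARTIAL,,NONE
1,1/8,2.35,0.15,6.3,31.61,FULL,36.67,FULL,37.10,FULL
1/2,1/8,2.35,0.07,3.1,32.04,FULL,37.45,PARTIAL,38.10,PARTIAL
1/4,1/8,2.35,0.04,1.6,31.93,FULL,38.14,PARTIAL,38.48,PARTIAL
1/8,1/8,2.35,0.02,0.8,31.81,FULL,37.96,PARTIAL,,NONE
1/16,1/8,2.35,0.01,0.4,31.92,FULL,41.02,PARTIAL,38.93,PARTIAL
1/32,1/8,2.35,0.005,0.2,31.64,FULL,,NONE,,NONE
1/64,1/8,2.35,0.002,0.1,31.62,FULL,,NONE,,NONE
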