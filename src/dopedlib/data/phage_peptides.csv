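id,sequence,ec50_gcgr,sd_gcgr,ec50_glp1r,sd_glp1r,ratio_printed
1,HSVGNFWSDYSKYLDSRRAQDFVQWLMLT,8.445,2.667,16.68,10.30,0.51
2,HSQGTFTSDYSKYVEDRRAHDFVQWLMNT,2.239,0.334,0.184,0.006,12.17
3,HSQGTFTSDYRKYLDERAAWDFVQWLMNT,1.351,0.173,0.427,0.022,3.16
4,HSQGTFTSDYSKYLDIGRAQDFVQWLLNT,0.026,0.002,1.328,0.209,0.02
5,HSQGTFTSDYSKYLDSLMAQDFVQWLMST,0.025,0.001,0.133,0.032,0.19
6,HSQGTFTSDYSKYLDWRRAQDFVQWLLNT,0.032,0.013,0.063,0.034,0.51
7,HSQGTFTSDYIKLLDSRRAQDFVQWLMNT,0.301,0.216,78.32,93.80,0.01
8,HSQGTFTSDYSKYLDARRAQDFVQWLIRT,0.038,0.010,0.017,0.001,2.23
9,HSQGTFTSDYSKYLDVRRAQDFVQWLMNT,0.022,0.007,0.064,0.015,0.34
10,HSQGTFTSDYSKYLDELRAYDFVQWLMNT,0.057,0.021,0.038,0.009,1.50
11,HSQGTFTSDYSKYLDSRRAHDFVQWLLNT,0.018,0.005,0.018,0.001,1
12,HSQGTFTSDYSKYLDSRRAQDFVQWLMNP,0.040,0.019,0.124,0.027,0.32
13,HSQGTFTSDYSKYLDSRRAQDFVQWLINY,0.078,0.050,0.039,0.008,2
14,INHEQWAFTSDYSKYLDSRRAQDFVQWLMNT,2.604,3.682,16.68,10.30,0.16
15,ASMFTFFSDYSKYLDSRRAQDFVQWLMLT,>20,,>200,,nd
16,HSQGTFLSDYSKLLDSRRAQDFVQWLMQT,0.131,0.060,11.22,10.56,0.01
17,HSQGTFLHDYYYYLDSRRAQDFVQWLMDT,0.527,0.315,>200,,nd
18,HSQGTFTSDYSKYLDSIRAQDFVQWLMDT,0.037,0.011,0.056,0.012,0.66
19,HSQGTFTSDYSKYLDSRRAQDFVDWLMNE,0.014,0.001,0.055,0.006,0.25
20,HSQGTFTSDYSKYLDSRRAQDFVQWLINT,0.031,0.004,0.017,0.002,1.82
21,KALGQFTFTSDYSKYLDSRRAQDFVQWLMNT,4.184,1.134,14.83,11.42,0.28
22,HSQGTFFSDYSHWLDSRRAQDFVQWLMNT,0.029,0.001,>200,,nd
23,HSQGTFTSDYSKYLDWRRAQDFVQWLQNT,0.019,0.001,0.017,0.001,1.12
24,HSQGTFTSDYSKYLDSKRAHDFVQWLLNT,0.026,0.001,0.018,0.001,1.44
25,HSQGTFTSDYSKYLDSRRAQDFWIDLMNT,>20,,>20,,nd
26,HSQGTFTSDYSKYLDSRRAQDFVMTSMNT,>200,,8.957,1.840,nd
27,HSQGTFTSDYSKYLDSRRAQDFVEWLMNN,0.015,0.003,0.029,0.001,0.52
28,HSQGTFTSDYSKYLDSRRAQDFVDWLINS,0.016,0.001,0.007,0.001,2.28
29,HSHGTFTSDYSKYLDSRRAQDFVQWLMTT,0.032,0.003,0.080,0.006,0.40
30,HSQGIFFSDYSKYLDSRRAQDFVQWLMNT,0.026,0.004,>200,,nd
31,HSQGTFTSDYSWYLDSRRAQDFVQWLMNT,0.032,0.011,0.044,0.004,0.73
32,HSQGTFTSDYSKYLDMQRAHDFVQWLMNT,0.014,0.001,0.022,0.001,0.64
33,HSQGTFTSDYSKYLDSRMAYDFVQWLMNT,0.079,0.033,0.059,0.003,1.34
34,HSQGTFFSDYSKYLDSRRAQDFVQWLLET,0.027,0.005,51.94,57.71,0.001
35,HSQGTFTSDYSKYLDSRRAQDFVQWLLDS,0.0019,0.005,0.018,0.001,0.10
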