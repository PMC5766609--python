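id,sequence,ec50_gcgr,sd_gcgr,ec50_glp1r,sd_glp1r,parent_id
11,HSQGTFTSDYSKYLDSRRAHDFVQWLLNT,0.018,0.005,0.018,0.001,
36,HsQGTFTSDK(γEγEC16)SKYLDSRRAHDFVQWLLNT,0.023,0.004,0.050,0.006,11
16,HSQGTFLSDYSKLLDSRAAQDFVQWLMQT,0.131,0.060,11.22,10.56,
37,HsQGTFLSDK(γEγEC16)SKLLDSRAAQDFVQWLMQT,0.037,0.004,23.48,7.599,16
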