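mass_g,s_mGy_per_MBq_h
0.01,5560.297643069969
0.02,2878.1905579941113
0.05,1205.2483230644284
0.1,623.8756566936217
0.2,322.9382921067059
0.5,135.23108604947836
1.0,70.0
2.0,36.234272334448214
5.0,15.173177414281156
10.0,7.854129180113745
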