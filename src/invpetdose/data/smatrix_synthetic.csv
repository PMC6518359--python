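organ,mass_g,liver,kidneys,spleen,lungs,brain,stomach,intestines,remainder,tissue_weight
liver,1800,0.0383333,4.64646e-05,2.35897e-05,1.51815e-05,9.57735e-07,4.38095e-05,1.05747e-05,2.44941e-06,0.04
kidneys,310,0.000269795,0.222581,5.52995e-05,4.17992e-05,4.55874e-06,6.79636e-05,0.000109916,1.94394e-05,0.02
spleen,180,0.000235897,9.52381e-05,0.383333,9.29293e-05,9.20921e-06,0.000807018,7.33652e-05,2.22222e-05,0.02
lungs,1000,2.73267e-05,1.29577e-05,1.67273e-05,0.069,3.06326e-06,3.68e-05,5.69072e-06,2.25122e-06,0.12
brain,1400,1.23137e-06,1.00944e-06,1.18404e-06,2.18805e-06,0.0492857,1.41321e-06,7.28809e-07,4.665e-07,0.01
stomach,150,0.000525714,0.000140458,0.000968421,0.000245333,1.319e-05,0.46,7.33068e-05,2.2716e-05,0.12
intestines,1000,1.90345e-05,3.40741e-05,1.32057e-05,5.69072e-06,1.02033e-06,1.0996e-05,0.069,1.62353e-05,0.12
remainder,68160,6.46852e-08,8.84126e-08,5.86854e-08,3.30285e-08,9.58186e-09,4.99913e-08,2.38194e-07,0.00101232,0.55
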