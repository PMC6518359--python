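region,units,fbp_ramp,fbp_butterworth,fbp_hamming,fbp_hanning,fbp_parzen,fbp_3drp,osem2d_iter1,osem2d_iter2,osem2d_iter3,osem2d_iter4,osem2d_iter5,osem2d_iter6,osem2d_iter7,osem2d_iter8,osem2d_iter9,osem2d_iter10,mapem_beta0.1,mapem_beta1.0,mapem_beta1.5
Tumor,mGy/MBq,1200.0,923.0,1020.0,1060.0,1020.0,1250.0,1320.0,1340.0,1440.0,1480.0,1560.0,1620.0,1660.0,1710.0,1760.0,1830.0,1380.0,1500.0,1180.0
Adrenals,mSv/MBq,0.0122,0.0094,0.0106,0.0104,0.0175,0.0121,0.0122,0.014,0.0159,0.0175,0.019,0.0206,0.0219,0.0227,0.0259,0.0911,0.0127,0.0141,0.0113
Brain,mSv/MBq,0.0327,0.0216,0.0222,0.0215,0.0556,0.0236,0.0263,0.0367,0.0466,0.0556,0.0642,0.0756,0.0775,0.0823,0.0899,0.32,0.0233,0.0283,0.0207
Breasts,mSv/MBq,0.0036,0.0027,0.0031,0.003,0.0053,0.0035,0.0037,0.0042,0.0048,0.0053,0.0057,0.0064,0.0066,0.0067,0.0077,0.0272,0.0036,0.004,0.0033
Gallbladder wall,mSv/MBq,0.0107,0.0084,0.0093,0.0092,0.0147,0.0109,0.0105,0.0121,0.0135,0.0147,0.0158,0.0174,0.018,0.0189,0.0211,0.0744,0.011,0.0124,0.0096
Lower large intestine wall,mSv/MBq,0.0031,0.0023,0.0026,0.0026,0.0044,0.0031,0.0032,0.0036,0.004,0.0044,0.0048,0.0053,0.0055,0.0058,0.0066,0.0231,0.0034,0.0038,0.003
Small intestine,mSv/MBq,0.0041,0.0032,0.0036,0.0035,0.0057,0.0041,0.0041,0.0047,0.0052,0.0057,0.0062,0.0067,0.0071,0.0075,0.0084,0.0296,0.0043,0.0048,0.0038
Stomach wall,mSv/MBq,0.106,0.0906,0.0947,0.0937,0.123,0.111,0.101,0.109,0.116,0.123,0.13,0.142,0.144,0.156,0.182,0.627,0.0993,0.1,0.0925
Upper lower intestine wall,mSv/MBq,0.0046,0.0036,0.004,0.004,0.0063,0.0047,0.0046,0.0052,0.0058,0.0063,0.0069,0.0075,0.0078,0.0083,0.0093,0.0327,0.0048,0.0053,0.0043
Heart wall,mSv/MBq,0.0084,0.0064,0.0072,0.0071,0.0123,0.0084,0.0086,0.0097,0.0112,0.0123,0.0133,0.0148,0.0152,0.0155,0.0179,0.0629,0.0086,0.0094,0.0077
Kidneys,mSv/MBq,0.189,0.146,0.165,0.157,0.268,0.187,0.18,0.213,0.242,0.268,0.293,0.285,0.339,0.36,0.404,1.41,0.183,0.203,0.172
Liver,mSv/MBq,0.0944,0.0746,0.0828,0.0821,0.13,0.0979,0.0924,0.107,0.119,0.13,0.139,0.155,0.158,0.166,0.181,0.644,0.099,0.113,0.084
Lungs,mSv/MBq,0.166,0.124,0.141,0.139,0.259,0.163,0.177,0.198,0.236,0.259,0.28,0.314,0.32,0.322,0.375,1.32,0.165,0.179,0.153
Muscle,mSv/MBq,0.0035,0.0027,0.003,0.003,0.0051,0.0035,0.0035,0.0041,0.0046,0.0051,0.0055,0.0061,0.0063,0.0066,0.0075,0.0264,0.0037,0.004,0.0033
Ovaries,mSv/MBq,0.0031,0.0023,0.0027,0.0026,0.0045,0.0032,0.0032,0.0037,0.0041,0.0045,0.0049,0.0054,0.0057,0.006,0.0067,0.0236,0.0035,0.0039,0.0031
Pancreas,mSv/MBq,0.0164,0.0127,0.0143,0.0141,0.0228,0.0162,0.0163,0.0187,0.0208,0.0228,0.0248,0.0276,0.0287,0.0297,0.0346,0.121,0.0174,0.019,0.0154
Red. Marrow,mSv/MBq,0.0038,0.0029,0.0033,0.0032,0.0056,0.0037,0.0038,0.0044,0.0051,0.0056,0.0062,0.0068,0.0071,0.0074,0.0084,0.0296,0.0039,0.0043,0.0035
Osteogenic,mSv/MBq,0.0031,0.0023,0.0026,0.0026,0.0047,0.003,0.0031,0.0036,0.0042,0.0047,0.0051,0.0057,0.0059,0.0061,0.007,0.0245,0.0031,0.0035,0.0028
Skin,mSv/MBq,0.0017,0.0013,0.0015,0.0014,0.0025,0.0017,0.0017,0.002,0.0023,0.0025,0.0027,0.003,0.0032,0.0033,0.0037,0.0131,0.0018,0.0019,0.0016
Spleen,mSv/MBq,0.448,0.326,0.385,0.382,0.673,0.412,0.462,0.538,0.604,0.673,0.746,0.862,0.894,0.899,1.09,3.8,0.539,0.596,0.459
Thymus,mSv/MBq,0.0038,0.0029,0.0033,0.0032,0.0058,0.0038,0.004,0.0045,0.0053,0.0058,0.0063,0.007,0.0072,0.0073,0.0084,0.0296,0.0039,0.0042,0.0035
Thyroid,mSv/MBq,0.0014,0.001,0.0011,0.0011,0.0021,0.0013,0.0014,0.0016,0.0019,0.0021,0.0023,0.0026,0.0027,0.0027,0.0031,0.011,0.0013,0.0015,0.0012
Urinary bladder,mSv/MBq,0.159,0.114,0.134,0.132,0.238,0.16,0.168,0.194,0.216,0.238,0.258,0.289,0.297,0.316,0.35,1.23,0.187,0.212,0.162
Uterus,mSv/MBq,0.005,0.0037,0.0042,0.0042,0.0073,0.005,0.0052,0.006,0.0067,0.0073,0.008,0.0089,0.0092,0.0097,0.0108,0.0381,0.0057,0.0064,0.005
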