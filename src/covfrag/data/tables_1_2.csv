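compound_id,warhead,benchmark,mis_mM,mfs_mM,qplogp,qplogs_mM,t_half_gsh_h,t_half_gsh_sd_h,t_half_pbs_h,k2_dtnb,k2_dtnb_sd,plateau_fit,note
Afatinib,none,1,,,,,1.1,0.0,>100,na,,0,a
Iodoacetamide,none,1,,,,,na,,na,2.6,0.1,0,b
AA001,AA,0,5.0,5.0,0.65,63,>100,,>100,0.018,0.005,0,
AA002,AA,0,5.0,5.0,2.2,5.0,>100,,>100,-0.0033,0.0001,0,
AA003,AA,0,5.0,5.0,1.1,20,130,,>100,0.00082,0.00012,0,
AA004,AA,0,1.0,1.0,1.6,6.5,<<0.033,,>100,0.0021,0.0012,0,c
AA005,AA,0,2.0,2.0,1.4,16,na,,na,na,,0,d
AA006,AA,0,5.0,5.0,1.6,5.6,>100,,>100,0.0078,0.0008,0,
AA007,AA,0,5.0,5.0,1.5,6.4,2.2,0.0,>100,0.0051,0.0009,0,
AA008,AA,0,5.0,5.0,0.89,3.0,>100,,>100,0.0039,0.0015,0,e
CA006,CA,0,5.0,5.0,0.32,7.1,>100,,61,-0.0050,0.0009,0,
CA007,CA,0,5.0,5.0,0.65,0.23,0.39,0.33,>100,0.0018,0.0012,1,f
CA008,CA,0,2.0,1.6,-0.26,3.6,na,,na,na,,0,d
EO004,EO,0,5.0,5.0,0.59,38,na,,na,-0.0083,0.0013,0,b
EO005,EO,0,5.0,5.0,1.6,40,20,0,47,0.012,0.001,0,
EO006,EO,0,5.0,5.0,0.89,107,na,,na,-0.024,0.002,0,b
EO007,EO,0,na,na,1.4,111,na,,na,na,,0,g
EO008,EO,0,3.2,4.0,-0.27,490,5.2,0.1,5.9,0.0027,0.0008,0,
EO009,EO,0,5.0,5.0,1.6,15,na,,na,-0.022,0.002,0,b
EO010,EO,0,3.2,5.0,1.5,13,30,6,9,0.013,0.001,0,
SN013,SN,0,5.0,5.0,1.0,50,>100,,>100,-0.0033,0.0012,0,
SN014,SN,0,3.2,3.2,1.7,16,47,1,88,-0.0047,0.0018,0,
SN015,SN,0,5.0,5.0,0.70,7.2,>100,,>100,0.025,0.001,0,
SN016,SN,0,1.6,1.6,1.8,11,230,,>100,0.23,0.01,0,
SN017,SN,0,2.6,2.6,0.71,12,0.13,0.00,23,0.43,0.00,0,
SN018,SN,0,5.0,5.0,-0.28,108,na,,na,na,,0,d
SN019,SN,0,5.0,5.0,1.2,67,0.81,0.04,>100,1.4,0.0,0,
SN020,SN,0,5.0,5.0,0.44,59,>100,,>100,0.018,0.001,0,
SN021,SN,0,5.0,5.0,0.44,61,>100,,>100,-0.018,0.002,0,i
SN022,SN,0,5.0,5.0,0.91,1.8,<<0.33,,>100,0.090,0.002,0,h
SN023,SN,0,5.0,5.0,1.3,12,>100,,>100,0.00028,0.00111,0,
SN024,SN,0,5.0,5.0,-0.39,333,>100,,>100,0.018,0.001,0,
SN025,SN,0,5.0,5.0,-0.30,106,>100,,>100,-0.0016,0.0006,0,
SN026,SN,0,5.0,5.0,0.13,6.5,4.7,0.2,>100,0.039,0.001,0,
SN027,SN,0,5.0,5.0,0.91,21,>100,,>100,0.0019,0.0010,0,
SN028,SN,0,5.0,2.6,0.91,21,na,,na,na,,0,d
SN029,SN,0,1.3,1.3,1.3,14,>100,,>100,0.0050,0.0008,0,
SN030,SN,0,5.0,5.0,1.2,14,2.1,0.2,>100,0.022,0.002,0,
SN031,SN,0,2.0,2.0,1.2,38,na,,na,na,,0,d
SN032,SN,0,2.6,1.3,0.81,1.2,na,,na,na,,0,d
SN033,SN,0,2.6,2.6,0.40,5.2,>100,,>100,0.026,0.001,0,
SN034,SN,0,na,na,2.4,0.85,na,,na,na,,0,g
SN035,SN,0,5.0,5.0,2.4,0.83,350,,>100,0.012,0.001,0,
SN036,SN,0,1.0,0.43,2.2,0.58,9.1,0.1,2.9,0.015,0.001,0,
SN037,SN,0,5.0,5.0,1.0,45,4.2,0.0,>100,0.035,0.001,0,
SN038,SN,0,5.0,5.0,1.4,11,<<0.033,,0.56,0.043,0.000,0,c
SN039,SN,0,5.0,5.0,1.9,0.62,1.6,0.1,>100,0.20,0.00,0,
SN040,SN,0,2.0,5.0,1.1,4.1,47,1,7.6,-0.0042,0.0011,0,
SN041,SN,0,4.0,5.0,1.1,4.1,96,4,91,-0.0023,0.0009,0,
SN042,SN,0,5.0,5.0,0.35,55,3.0,0.2,15,0.028,0.001,0,
SN043,SN,0,5.0,5.0,1.4,6.8,>100,,>100,0.022,0.001,0,
SN044,SN,0,4.0,3.2,1.8,3.6,na,,na,na,,0,d
SN045,SN,0,5.0,5.0,1.4,17,51,10,>100,0.043,0.000,0,
SN046,SN,0,5.0,5.0,0.67,47,1.5,0.1,>100,0.033,0.001,0,
SN047,SN,0,5.0,5.0,0.46,643,>100,,>100,0.0078,0.0003,0,
SN048,SN,0,3.2,5.0,0.78,2.0,0.22,0.00,26,0.22,0.00,0,
SN049,SN,0,5.0,5.0,0.39,6.9,na,,na,na,,0,d
SN050,SN,0,5.0,5.0,1.2,3.2,0.14,0.00,44,2.4,0.1,0,
SN051,SN,0,5.0,5.0,2.4,11,>100,,>100,0.014,0.001,0,
SN052,SN,0,4.0,4.0,1.9,3.5,260,,>100,0.016,0.000,0,
SN053,SN,0,4.0,4.0,1.6,14,na,,na,na,,0,d
SN054,SN,0,0.67,0.67,0.62,66,0.17,0.00,>100,0.12,0.00,0,
SN055,SN,0,5.0,5.0,0.45,49,2.1,0.1,>100,0.015,0.00,0,
SN056,SN,0,5.0,5.0,0.45,50,26,1,4.9,0.015,0.00,0,
SN057,SN,0,2.6,2.0,1.3,37,>100,,>100,0.025,0.000,0,
SN058,SN,0,5.0,5.0,0.96,11,152,1,>100,0.0022,0.001,0,
SN059,SN,0,5.0,5.0,0.54,6.8,>100,,>100,0.032,0.001,0,
SN060,SN,0,5.0,5.0,1.5,8.0,0.22,0.00,>100,1.4,0.0,0,
SN061,SN,0,5.0,5.0,0.56,46,na,,na,na,,0,d
SN062,SN,0,4.0,5.0,2.0,1.2,>100,,>100,0.027,0.001,0,
SN063,SN,0,5.0,5.0,0.67,10,8.1,0.2,>100,0.035,0.001,0,
SN064,SN,0,5.0,5.0,1.3,17,0.59,0.01,>100,0.14,0.00,0,
SN065,SN,0,5.0,5.0,1.4,11,>100,,>100,0.0040,0.0006,0,
SN066,SN,0,na,na,1.5,35,na,,na,na,,0,g
SN067,SN,0,0.67,0.67,1.0,12,1.1,0.0,>100,0.031,0.001,0,
SN068,SN,0,5.0,5.0,2.7,1.5,24,4,6.4,-0.011,0.001,0,
SN069,SN,0,5.0,5.0,-0.01,319,<<0.33,,5.2,7.2,0.1,0,h
SN070,SN,0,1.6,1.3,0.64,3.8,908,,>100,0.032,0.001,0,
SN071,SN,0,5.0,5.0,0.13,103,>100,,>100,0.019,0.001,0,
SN072,SN,0,5.0,5.0,1.3,913,>100,,>100,0.0022,0.0008,0,
VS005,VS,0,3.2,5.0,0.74,29,>100,,>100,-0.0080,0.0009,0,
VS006,VS,0,5.0,5.0,1.7,3.2,na,,na,0.0098,0.0012,0,b
VS007,VS,0,5.0,5.0,1.2,9.8,0.070,0.0,>100,0.25,0.00,0,
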