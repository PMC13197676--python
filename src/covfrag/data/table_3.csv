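compound_id,min_stabilizing_conc_uM,first_stabilizing_time,first_stabilizing_time_h,note
SN019,250,24 h,24,
SN022,62.5,10 min,0.167,
SN026,none,24 h,24,a
SN028,125,24 h,24,
SN038,125,10 min,0.167,
SN039,500,24 h,24,
SN042,500,24 h,24,
SN046,500,24 h,24,
SN048,none,24 h,24,a
SN054,15.63,10 min,0.167,
SN055,1000,24 h,24,
SN060,31.25,1 h,1,
SN061,none,24 h,24,a
VS006,250,24 h,24,
VS007,1000,10 min,0.167,
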