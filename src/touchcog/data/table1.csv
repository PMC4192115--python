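subject,sex,age_years,training_days,positive_image,first_session_bias,pd_bias_excluded,pd_sessions,pd_trials,pd_response_latency,pd_reward_latency,pdr_sessions,pdr_trials,pdr_response_latency,pdr_reward_latency,persev_errors_binomial,persev_errors_50,trials_to_50
OTT,m,2.0,13,marble,,0,5,150,5.156,1.619,11,330,4.255,1.448,64,110,180
PEA,m,2.6,48,fan,,0,19,570,7.563,2.198,14,420,3.040,1.285,82,111,180
PED,m,2.1,24,fan,,0,8,240,4.607,2.088,9,270,3.352,1.459,66,90,150
PEP,m,2.3,14,fan,,0,7,210,2.481,0.919,15,450,2.071,0.972,50,157,270
PPP,m,2.0,31,marble,,0,8,233,3.997,2.071,17,426,14.461,2.609,189,219,306
PHI,m,2.3,71,fan,marble,1,22,614,12.296,27.673,25,682,17.415,24.229,65,159,263
PLU,m,2.1,25,marble,marble,1,3,90,3.134,1.220,20,570,8.104,1.057,82,149,241
QUK,m,3.2,35,fan,marble,1,16,470,11.559,4.475,16,340,19.330,59.989,78,150,250
QUN,m,3.0,11,marble,,0,13,381,4.664,1.539,18,540,3.629,1.302,122,213,330
QUL,m,3.5,36,marble,,0,19,570,3.635,1.410,26,780,2.012,0.865,100,164,270
NEL,f,1.2,38,marble,fan,1,12,215,8.843,1.743,16,381,5.679,1.520,98,185,261
NOR,f,1.1,20,marble,,0,4,120,5.040,1.286,13,319,17.903,2.559,40,127,229
PAM,f,3.1,26,fan,marble,1,18,437,10.013,1.290,15,358,6.954,1.031,61,162,238
PAU,f,3.0,9,marble,,0,12,360,3.785,1.802,32,960,3.676,1.015,216,367,600
PEG,f,2.5,17,fan,,0,5,150,5.598,1.325,7,210,7.472,1.428,58,87,180
PEN,f,2.9,6,fan,,0,6,180,5.433,2.976,9,245,20.064,2.830,67,108,154
PER,f,3.1,13,fan,,0,9,237,9.946,1.787,7,208,3.705,1.749,46,84,148
POP,f,2.4,32,marble,,0,4,120,3.117,1.405,11,285,43.976,32.011,27,96,165
QNI,f,4.1,10,marble,,0,7,210,3.486,1.591,18,540,2.887,1.473,140,198,300
QEL,f,3.9,17,fan,,0,6,180,7.460,0.935,13,390,7.641,0.982,102,191,330
ULI,m,7.8,12,fan,,0,25,574,56.709,15.055,20,600,4.042,1.210,228,274,360
URB,m,7.5,20,marble,marble,1,6,180,3.630,1.623,19,539,12.569,1.503,147,277,419
URI,m,7.4,33,marble,,0,14,420,19.202,2.462,34,1020,8.803,1.539,89,434,750
VIR,m,8.6,22,fan,,0,26,780,6.174,1.217,24,617,9.035,2.108,100,195,350
TIP,f,6.9,6,marble,,0,19,570,2.844,3.348,33,979,6.530,1.398,447,493,769
UND,f,7.8,33,fan,,0,8,191,10.928,2.888,14,375,5.896,2.531,14,152,284
URA,f,7.9,9,marble,,0,10,300,5.037,1.796,11,330,8.666,1.408,73,122,180
URS,f,7.6,19,fan,,0,9,270,5.379,1.314,9,300,4.420,1.714,64,91,150
VAN,f,8.4,14,fan,,0,11,330,5.757,1.721,21,630,5.955,1.870,171,229,330
WIL,f,9.5,63,marble,,0,26,780,3.061,2.678,60,1800,4.615,2.852,797,1001,1680
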