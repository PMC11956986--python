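lab_id,lab_name,n_tested,n_included,condition,frequency_hz,mean_uv,sd_uv
1,braindynlab,17,11,control,0.8,-0.025,0.034
1,braindynlab,17,11,control,1.2,-0.01,0.029
1,braindynlab,17,11,control,1.6,0.001,0.021
1,braindynlab,17,11,control,2.4,0.068,0.044
1,braindynlab,17,11,binary,0.8,-0.019,0.032
1,braindynlab,17,11,binary,1.2,0.025,0.041
1,braindynlab,17,11,binary,1.6,-0.003,0.013
1,braindynlab,17,11,binary,2.4,0.074,0.07
1,braindynlab,17,11,ternary,0.8,0.002,0.031
1,braindynlab,17,11,ternary,1.2,0.006,0.017
1,braindynlab,17,11,ternary,1.6,0.01,0.016
1,braindynlab,17,11,ternary,2.4,0.071,0.036
2,capslab,14,12,control,0.8,-0.004,0.05
2,capslab,14,12,control,1.2,0.005,0.031
2,capslab,14,12,control,1.6,-0.017,0.024
2,capslab,14,12,control,2.4,0.066,0.033
2,capslab,14,12,binary,0.8,0.049,0.078
2,capslab,14,12,binary,1.2,0.03,0.05
2,capslab,14,12,binary,1.6,-0.015,0.025
2,capslab,14,12,binary,2.4,0.079,0.046
2,capslab,14,12,ternary,0.8,0.016,0.041
2,capslab,14,12,ternary,1.2,0.016,0.086
2,capslab,14,12,ternary,1.6,-0.0004,0.033
2,capslab,14,12,ternary,2.4,0.067,0.053
3,cogsci-vassar,15,11,control,0.8,-0.095,0.322
3,cogsci-vassar,15,11,control,1.2,-0.002,0.04
3,cogsci-vassar,15,11,control,1.6,0.052,0.171
3,cogsci-vassar,15,11,control,2.4,0.062,0.037
3,cogsci-vassar,15,11,binary,0.8,-0.034,0.093
3,cogsci-vassar,15,11,binary,1.2,0.036,0.064
3,cogsci-vassar,15,11,binary,1.6,-0.009,0.051
3,cogsci-vassar,15,11,binary,2.4,0.059,0.056
3,cogsci-vassar,15,11,ternary,0.8,-0.005,0.054
3,cogsci-vassar,15,11,ternary,1.2,0.008,0.03
3,cogsci-vassar,15,11,ternary,1.6,-0.0005,0.024
3,cogsci-vassar,15,11,ternary,2.4,0.071,0.04
4,dvplab,17,16,control,0.8,0.018,0.024
4,dvplab,17,16,control,1.2,-0.002,0.023
4,dvplab,17,16,control,1.6,-0.0001,0.024
4,dvplab,17,16,control,2.4,0.035,0.034
4,dvplab,17,16,binary,0.8,0.014,0.027
4,dvplab,17,16,binary,1.2,0.049,0.066
4,dvplab,17,16,binary,1.6,-0.019,0.022
4,dvplab,17,16,binary,2.4,0.091,0.08
4,dvplab,17,16,ternary,0.8,0.059,0.069
4,dvplab,17,16,ternary,1.2,0.009,0.033
4,dvplab,17,16,ternary,1.6,0.023,0.068
4,dvplab,17,16,ternary,2.4,0.089,0.115
5,grahnlab,11,8,control,0.8,-0.001,0.037
5,grahnlab,11,8,control,1.2,-0.007,0.015
5,grahnlab,11,8,control,1.6,-0.008,0.014
5,grahnlab,11,8,control,2.4,0.059,0.025
5,grahnlab,11,8,binary,0.8,-0.008,0.019
5,grahnlab,11,8,binary,1.2,0.031,0.029
5,grahnlab,11,8,binary,1.6,-0.004,0.025
5,grahnlab,11,8,binary,2.4,0.09,0.038
5,grahnlab,11,8,ternary,0.8,0.018,0.022
5,grahnlab,11,8,ternary,1.2,-0.012,0.015
5,grahnlab,11,8,ternary,1.6,0.004,0.019
5,grahnlab,11,8,ternary,2.4,0.079,0.042
6,huettig,14,10,control,0.8,0.007,0.036
6,huettig,14,10,control,1.2,-0.012,0.018
6,huettig,14,10,control,1.6,-0.004,0.013
6,huettig,14,10,control,2.4,0.067,0.044
6,huettig,14,10,binary,0.8,-0.007,0.019
6,huettig,14,10,binary,1.2,0.018,0.02
6,huettig,14,10,binary,1.6,0.003,0.027
6,huettig,14,10,binary,2.4,0.076,0.06
6,huettig,14,10,ternary,0.8,0.012,0.028
6,huettig,14,10,ternary,1.2,0.002,0.033
6,huettig,14,10,ternary,1.6,0.009,0.015
6,huettig,14,10,ternary,2.4,0.065,0.036
7,labnpf,17,9,control,0.8,0.002,0.033
7,labnpf,17,9,control,1.2,0.021,0.035
7,labnpf,17,9,control,1.6,-0.008,0.015
7,labnpf,17,9,control,2.4,0.034,0.037
7,labnpf,17,9,binary,0.8,-0.022,0.041
7,labnpf,17,9,binary,1.2,0.009,0.041
7,labnpf,17,9,binary,1.6,0.007,0.025
7,labnpf,17,9,binary,2.4,0.055,0.054
7,labnpf,17,9,ternary,0.8,0.039,0.041
7,labnpf,17,9,ternary,1.2,-0.004,0.025
7,labnpf,17,9,ternary,1.6,0.011,0.024
7,labnpf,17,9,ternary,2.4,0.075,0.056
8,mib-au,16,8,control,0.8,-0.017,0.031
8,mib-au,16,8,control,1.2,-0.009,0.026
8,mib-au,16,8,control,1.6,-0.004,0.019
8,mib-au,16,8,control,2.4,0.041,0.036
8,mib-au,16,8,binary,0.8,-0.023,0.032
8,mib-au,16,8,binary,1.2,-0.007,0.027
8,mib-au,16,8,binary,1.6,0.001,0.026
8,mib-au,16,8,binary,2.4,0.047,0.045
8,mib-au,16,8,ternary,0.8,0.024,0.028
8,mib-au,16,8,ternary,1.2,0.005,0.028
8,mib-au,16,8,ternary,1.6,0.001,0.017
8,mib-au,16,8,ternary,2.4,0.046,0.036
9,mindlab,16,13,control,0.8,0.045,0.187
9,mindlab,16,13,control,1.2,-0.012,0.035
9,mindlab,16,13,control,1.6,-0.006,0.032
9,mindlab,16,13,control,2.4,0.047,0.073
9,mindlab,16,13,binary,0.8,-0.02,0.094
9,mindlab,16,13,binary,1.2,0.053,0.079
9,mindlab,16,13,binary,1.6,-0.01,0.065
9,mindlab,16,13,binary,2.4,0.098,0.075
9,mindlab,16,13,ternary,0.8,0.069,0.075
9,mindlab,16,13,ternary,1.2,0.015,0.059
9,mindlab,16,13,ternary,1.6,0.017,0.06
9,mindlab,16,13,ternary,2.4,0.089,0.087
10,bdl-uakl,16,11,control,0.8,-0.004,0.061
10,bdl-uakl,16,11,control,1.2,0.001,0.041
10,bdl-uakl,16,11,control,1.6,0.006,0.02
10,bdl-uakl,16,11,control,2.4,0.055,0.038
10,bdl-uakl,16,11,binary,0.8,-0.025,0.042
10,bdl-uakl,16,11,binary,1.2,0.09,0.171
10,bdl-uakl,16,11,binary,1.6,0.005,0.021
10,bdl-uakl,16,11,binary,2.4,0.107,0.06
10,bdl-uakl,16,11,ternary,0.8,0.055,0.081
10,bdl-uakl,16,11,ternary,1.2,-0.03,0.044
10,bdl-uakl,16,11,ternary,1.6,0.026,0.071
10,bdl-uakl,16,11,ternary,2.4,0.115,0.065
11,smartlab,11,10,control,0.8,-0.028,0.054
11,smartlab,11,10,control,1.2,-0.039,0.046
11,smartlab,11,10,control,1.6,-0.035,0.081
11,smartlab,11,10,control,2.4,0.067,0.078
11,smartlab,11,10,binary,0.8,0.013,0.086
11,smartlab,11,10,binary,1.2,0.054,0.047
11,smartlab,11,10,binary,1.6,-0.017,0.018
11,smartlab,11,10,binary,2.4,0.118,0.077
11,smartlab,11,10,ternary,0.8,0.071,0.116
11,smartlab,11,10,ternary,1.2,-0.003,0.03
11,smartlab,11,10,ternary,1.6,0.03,0.092
11,smartlab,11,10,ternary,2.4,0.102,0.038
12,unlv-acnl,23,19,control,0.8,-0.0004,0.055
12,unlv-acnl,23,19,control,1.2,-0.003,0.033
12,unlv-acnl,23,19,control,1.6,-0.014,0.04
12,unlv-acnl,23,19,control,2.4,0.085,0.043
12,unlv-acnl,23,19,binary,0.8,0.008,0.062
12,unlv-acnl,23,19,binary,1.2,0.011,0.029
12,unlv-acnl,23,19,binary,1.6,0.006,0.033
12,unlv-acnl,23,19,binary,2.4,0.078,0.041
12,unlv-acnl,23,19,ternary,0.8,0.011,0.061
12,unlv-acnl,23,19,ternary,1.2,0.01,0.026
12,unlv-acnl,23,19,ternary,1.6,0.005,0.021
12,unlv-acnl,23,19,ternary,2.4,0.066,0.038
13,keitellab,17,14,control,0.8,-0.042,0.029
13,keitellab,17,14,control,1.2,-0.009,0.044
13,keitellab,17,14,control,1.6,-0.008,0.021
13,keitellab,17,14,control,2.4,0.043,0.045
13,keitellab,17,14,binary,0.8,-0.021,0.059
13,keitellab,17,14,binary,1.2,0.043,0.056
13,keitellab,17,14,binary,1.6,-0.011,0.026
13,keitellab,17,14,binary,2.4,0.093,0.078
13,keitellab,17,14,ternary,0.8,-0.007,0.073
13,keitellab,17,14,ternary,1.2,-0.014,0.019
13,keitellab,17,14,ternary,1.6,0.026,0.041
13,keitellab,17,14,ternary,2.4,0.071,0.069
14,vumc-mtsu,8,4,control,0.8,-0.07,0.085
14,vumc-mtsu,8,4,control,1.2,0.003,0.024
14,vumc-mtsu,8,4,control,1.6,-0.009,0.014
14,vumc-mtsu,8,4,control,2.4,0.042,0.024
14,vumc-mtsu,8,4,binary,0.8,-0.001,0.032
14,vumc-mtsu,8,4,binary,1.2,0.045,0.036
14,vumc-mtsu,8,4,binary,1.6,-0.004,0.021
14,vumc-mtsu,8,4,binary,2.4,0.044,0.034
14,vumc-mtsu,8,4,ternary,0.8,0.08,0.079
14,vumc-mtsu,8,4,ternary,1.2,-0.009,0.051
14,vumc-mtsu,8,4,ternary,1.6,0.019,0.054
14,vumc-mtsu,8,4,ternary,2.4,0.051,0.028
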