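# Weibel-type morphometry of the human airway tree, 24 generations (z = 0 trachea,
# 1-19 bronchi, 20-23 alveolar region). Generation z has n = 2^z identical branches.
# Columns d/l are per-branch diameter/length (cm); s is the TOTAL cross-sectional
# area of the generation (cm^2); u is the mean air-flow velocity (cm/s).
# R_printed/L_printed/C_printed are the source table's own tabulated electrical-analogy
# values (cm H2O/(L/s), cm H2O/(L/s^2), L/cm H2O) and are shipped verbatim for
# validation; they are never recomputed silently. Known transcription notes:
# the z=0 compliance (0.06311) is ~10x below what the l*s/(rho*n*u^2) formula gives
# and is carried as printed; row 22 geometry (l=0.67, u=0.99) breaks the monotone
# trends of neighbouring rows and is likewise carried as printed.
z,n,d_cm,l_cm,s_cm2,u_cm_s,R_printed,L_printed,C_printed
0,1,1.8,12,2.54,197,0.0086,0.0059,0.06311
1,2,1.22,4.76,2.33,215,0.008,0.0025,0.0964
2,4,0.83,1.9,2.13,236,0.0075,0.0011,0.0145
3,8,0.56,0.76,2,251,0.0072,0.0004,0.0024
4,16,0.45,1.27,2.48,202,0.0145,0.0006,0.0038
5,32,0.35,1.07,3.11,161,0.0167,0.0004,0.0032
6,64,0.28,0.9,3.96,126,0.0172,0.0002,0.0028
7,128,0.23,0.76,5.1,98,0.0159,0.0001,0.0025
8,256,0.186,0.64,6.95,72,0.0157,0.0001,0.0026
9,512,0.154,0.54,9.56,52,0.0141,7.03e-5,0.0029
10,1024,0.13,0.46,13.4,37,0.0118,4.27e-5,0.0035
11,2048,0.109,0.39,19.6,26,0.0101,2.48e-5,0.0044
12,4096,0.095,0.33,28.8,17,0.0074,1.43e-5,0.0064
13,8192,0.082,0.27,44.5,11,0.0054,7.55e-6,0.0097
14,16384,0.074,0.16,69.4,7.2,0.0024,2.87e-6,0.0105
15,32768,0.05,0.13,117,4.3,0.0048,1.41e-6,0.0206
16,65536,0.049,0.11,225,2.2,0.0022,6.19e-7,0.0638
17,131072,0.04,0.09,300,1.7,0.002,3.86e-7,0.0591
18,262144,0.038,0.08,543,0.92,0.0011,1.90e-7,0.1632
19,524288,0.036,0.07,978,0.51,0.0005,8.91e-8,0.4034
20,1048576,0.034,0.07,1740,0.29,0.0003,5.01e-8,1.1099
21,2097152,0.031,0.07,2730,0.18,0.0002,3.19e-8,2.26
22,4194304,0.029,0.67,5070,0.99,0.0016,1.64e-7,0.664
23,8388608,0.025,0.07,7530,0.66,0.0001,1.24e-8,0.1241
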