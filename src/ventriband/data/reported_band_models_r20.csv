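plan,patient,rv_vol_bf_ml,stress_bf_kpa,strain_bf,rv_vol_be_ml,stress_be_kpa,strain_be,ef_pct,delta_ef_pct
A,P1,244.90,3.17,0.033,406.15,61.64,0.291,39.70,2.32
A,P2,248.20,3.20,0.029,408.42,46.61,0.314,39.23,1.79
A,P3,454.35,7.70,0.020,665.47,77.62,0.194,31.72,2.12
A,P4,186.00,3.46,0.019,327.59,54.74,0.308,43.22,2.98
A,P5,113.82,4.26,0.026,204.64,54.68,0.287,44.38,4.11
A,P6,100.39,3.13,0.022,204.14,58.03,0.418,50.82,1.94
A,P7,181.45,7.44,0.017,299.87,89.02,0.267,39.49,2.41
B,P1,246.47,3.16,0.032,407.07,64.72,0.285,39.45,2.07
B,P2,248.86,3.13,0.028,409.31,48.72,0.318,39.20,1.76
B,P3,455.69,6.99,0.019,662.07,76.83,0.192,31.17,1.57
B,P4,187.73,3.86,0.026,327.81,54.61,0.309,42.73,2.49
B,P5,115.45,4.52,0.030,203.80,54.03,0.287,43.35,3.08
B,P6,100.53,3.14,0.022,203.41,58.49,0.417,50.58,1.70
B,P7,181.57,7.30,0.018,299.74,88.49,0.266,39.43,2.35
C,P1,240.64,3.21,0.033,405.83,63.98,0.289,40.70,3.32
C,P2,246.21,3.37,0.033,408.79,49.39,0.313,39.77,2.33
C,P3,447.69,8.10,0.022,664.29,79.06,0.199,32.61,3.01
C,P4,180.69,3.76,0.025,327.32,59.38,0.312,44.80,4.56
C,P5,111.12,3.31,0.025,203.22,51.38,0.286,45.32,5.05
C,P6,99.36,3.32,0.025,203.19,57.93,0.418,51.10,2.22
C,P7,179.26,7.91,0.020,299.65,89.08,0.266,40.18,3.10
D,P1,243.71,2.92,0.031,400.63,64.86,0.306,39.17,1.79
D,P2,248.88,2.88,0.026,407.35,46.87,0.310,38.90,1.46
D,P3,455.90,6.70,0.021,663.89,77.39,0.199,31.33,1.73
D,P4,189.25,4.33,0.026,327.44,58.42,0.305,42.20,1.96
D,P5,116.50,4.92,0.030,204.46,53.37,0.283,43.02,2.75
D,P6,100.97,3.24,0.024,204.56,56.94,0.419,50.64,1.76
D,P7,182.88,6.72,0.017,299.91,86.88,0.265,39.02,1.94
E,P1,235.13,3.39,0.035,402.45,67.76,0.302,41.58,4.20
E,P2,243.04,3.53,0.037,408.20,51.56,0.315,40.46,3.02
E,P3,441.93,8.40,0.025,665.31,79.89,0.200,33.58,3.98
E,P4,178.64,4.11,0.028,327.18,59.69,0.312,45.40,5.16
E,P5,109.43,3.69,0.027,203.71,57.02,0.307,46.28,6.01
E,P6,98.20,3.73,0.030,203.52,59.39,0.423,51.75,2.87
E,P7,175.77,8.39,0.024,299.37,88.86,0.267,41.29,4.21
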