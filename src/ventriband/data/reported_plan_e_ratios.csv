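ratio,patient,rv_vol_bf_ml,stress_bf_kpa,strain_bf,rv_vol_be_ml,stress_be_kpa,strain_be,ef_pct,delta_ef_pct
0.00,P1,248.83,2.82,0.028,375.78,54.60,0.278,33.78,-3.60
0.00,P2,254.60,2.51,0.019,394.09,42.87,0.310,35.40,-2.04
0.00,P3,466.38,6.09,0.017,644.83,76.66,0.197,27.67,-1.93
0.00,P4,191.92,3.44,0.018,307.01,49.67,0.295,37.49,-2.75
0.00,P5,118.11,3.77,0.025,180.59,41.78,0.266,34.60,-5.67
0.00,P6,103.77,2.53,0.015,190.01,50.33,0.407,45.39,-3.49
0.00,P7,187.09,5.87,0.012,282.35,77.11,0.253,33.74,-3.34
0.10,P1,242.37,3.01,0.030,402.81,67.33,0.301,39.83,2.45
0.10,P2,249.85,2.79,0.025,407.67,48.72,0.314,38.71,1.27
0.10,P3,455.54,6.57,0.018,665.33,78.99,0.200,31.53,1.93
0.10,P4,186.16,3.54,0.021,327.86,58.67,0.313,43.22,2.98
0.10,P5,114.05,3.60,0.025,203.88,55.88,0.306,44.06,3.79
0.10,P6,101.27,2.90,0.020,203.72,58.17,0.422,50.29,1.41
0.10,P7,182.07,6.32,0.015,299.44,87.98,0.267,39.20,2.12
0.15,P1,238.86,3.18,0.032,402.66,67.47,0.301,40.68,3.30
0.15,P2,246.70,3.14,0.031,407.99,50.66,0.315,39.53,2.09
0.15,P3,449.11,7.37,0.021,665.58,79.25,0.200,32.52,2.92
0.15,P4,182.61,3.80,0.024,327.52,58.99,0.312,44.24,4.00
0.15,P5,111.80,3.61,0.025,203.81,56.41,0.306,45.15,4.88
0.15,P6,99.80,3.29,0.025,203.63,58.74,0.422,50.99,2.11
0.15,P7,179.07,7.23,0.019,299.54,88.72,0.267,40.22,3.14
0.20,P1,235.13,3.39,0.035,402.45,67.76,0.302,41.58,4.20
0.20,P2,243.04,3.53,0.037,408.20,51.56,0.315,40.46,3.02
0.20,P3,441.93,8.40,0.025,665.31,79.89,0.200,33.58,3.98
0.20,P4,178.64,4.11,0.028,327.18,59.69,0.312,45.40,5.16
0.20,P5,109.43,3.69,0.027,203.71,57.02,0.307,46.28,6.01
0.20,P6,98.20,3.73,0.030,203.52,59.39,0.423,51.75,2.87
0.20,P7,175.77,8.39,0.024,299.37,88.86,0.267,41.29,4.21
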