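model,plan,ratio,rv_vol_bf_mean,rv_vol_bf_sd,stress_bf_mean,stress_bf_sd,strain_bf_mean,strain_bf_sd,rv_vol_be_mean,rv_vol_be_sd,stress_be_mean,stress_be_sd,strain_be_mean,strain_be_sd,ef_mean,ef_sd,delta_ef_mean,delta_ef_sd
Baseline,,,226.84,121.20,4.22,1.63,0.022,0.008,359.19,158.41,62.89,14.81,0.292,0.062,38.71,5.73,,
A000,A,0.00,225.48,121.60,4.05,1.56,0.020,0.006,349.76,158.75,60.13,14.82,0.291,0.065,37.34,5.56,-1.37,0.50
A010,A,0.10,222.19,120.26,4.19,1.69,0.021,0.006,359.66,158.55,63.35,14.52,0.297,0.067,40.21,5.86,1.50,0.63
A015,A,0.15,220.41,119.53,4.38,1.84,0.022,0.005,359.41,158.49,63.41,14.52,0.297,0.067,40.67,5.87,1.96,0.75
A020,A,0.20,218.44,118.70,4.62,2.05,0.024,0.006,359.47,158.58,63.19,14.85,0.297,0.067,41.22,5.85,2.51,0.80
P000,B,0.00,226.01,144.44,4.17,1.58,0.021,0.007,352.08,157.36,61.01,14.74,0.293,0.065,37.67,5.52,-1.04,0.44
P010,B,0.10,223.02,120.21,4.17,1.56,0.022,0.006,359.43,157.91,63.45,14.26,0.297,0.067,39.89,5.83,1.18,0.37
P015,B,0.15,221.34,119.58,4.34,1.66,0.023,0.006,359.12,157.82,63.57,14.23,0.296,0.067,40.33,5.84,1.62,0.44
P020,B,0.20,219.47,118.89,4.59,1.82,0.025,0.006,359.03,157.84,63.70,14.23,0.296,0.067,40.84,5.84,2.13,0.53
AP000,C,0.00,225.02,121.37,3.88,1.59,0.019,0.006,344.56,157.62,57.99,15.86,0.287,0.064,36.39,5.43,-2.32,0.85
AP010,C,0.10,220.54,119.53,4.03,1.73,0.021,0.005,358.93,158.60,63.49,14.89,0.297,0.066,40.52,5.79,1.81,0.77
AP015,C,0.15,217.91,118.43,4.32,1.95,0.023,0.005,359.10,158.72,63.95,14.70,0.298,0.066,41.28,5.77,2.57,0.91
AP020,C,0.20,214.99,117.19,4.71,2.26,0.026,0.005,358.90,158.61,64.32,14.64,0.298,0.066,42.07,5.77,3.36,1.07
B000,D,0.00,225.72,121.25,4.08,1.58,0.021,0.006,350.83,157.53,59.57,14.05,0.293,0.066,37.48,5.76,-1.23,0.79
B010,D,0.10,223.21,120.01,4.14,1.54,0.022,0.006,358.94,157.96,63.17,14.05,0.298,0.066,39.73,5.82,1.02,0.32
B015,D,0.15,221.48,119.34,4.30,1.59,0.023,0.005,358.76,157.84,63.11,14.10,0.297,0.066,40.19,5.80,1.48,0.35
B020,D,0.20,219.73,118.50,4.53,1.67,0.025,0.005,358.32,157.72,63.53,14.08,0.298,0.066,40.61,5.81,1.90,0.40
APB000,E,0.00,224.39,121.35,3.86,1.52,0.019,0.006,339.24,157.82,56.15,14.84,0.287,0.064,35.44,5.32,-3.27,1.26
APB010,E,0.10,218.76,118.86,4.10,1.63,0.022,0.005,358.67,158.54,65.11,13.93,0.303,0.066,40.98,5.77,2.27,0.89
APB015,E,0.15,215.42,117.36,4.52,1.92,0.025,0.005,358.68,158.66,65.75,13.68,0.303,0.066,41.90,5.72,3.19,1.00
APB020,E,0.20,211.73,115.66,5.03,2.30,0.029,0.005,358.53,158.63,66.31,13.48,0.304,0.067,42.90,5.68,4.19,1.11
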