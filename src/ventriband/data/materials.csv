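region,phase,c1,c2,D1,D2,K1,K2
patch,end_ejection,26.52,0,26.52,9.0,0,1
patch,end_filling,26.52,0,26.52,9.0,0,1
scar,end_ejection,13.26,0,13.26,9.0,0,1
scar,end_filling,13.26,0,13.26,9.0,0,1
band,end_ejection,900,0,0,0,0,1
band,end_filling,70,0,0,0,0,1
myocardium_inner,end_ejection,7.64,0,2.41,3.0,36.55,3.0
myocardium_outer,end_ejection,8.72,0,2.24,3.0,35.52,3.2
myocardium_inner,end_filling,2.78,0,0.87,3.0,13.29,3.0
myocardium_outer,end_filling,3.17,0,0.82,3.0,12.92,3.2
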