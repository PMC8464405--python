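id,age,sex,pathology,alpha_deg,kappa_ip,kappa_op,c2,k1,k2,r2_theta_2f,r2_z_2f,c4,k1el,k2el,k1smc,k2smc,k1col,k2col,r2_theta_4f,r2_z_4f
1,12,F,None,61,0.21,0.38,3.22,24.4,0.04,0.95,0.94,7.68,10.63,0.2,0.67,0.52,12.28,0.75,0.99,0.99
2,25,F,None,49,0.12,0.39,15.28,11.59,3.54,0.66,0.91,6.13,10.96,0,2.19,3.96,17.77,2.88,0.99,0.97
3,26,M,Mild intimal thickening,51,0.15,0.37,26.71,13.19,4.17,0.75,0.92,13.46,13.41,0,3.56,2.18,18.12,4.43,0.98,0.97
4,28,M,Mild intimal thickening,43,0.15,0.42,9.82,9.53,3.61,0.73,0.96,3.36,12.06,0,2.79,5.23,9.74,4.29,0.99,0.98
5,38,F,Mild intimal thickening,46,0.17,0.42,4.13,11.98,2.27,0.84,0.83,3.6,9.43,1.12,1.91,1.93,5.11,4.65,0.99,0.98
6,47,F,Mild intimal thickening,36,0.14,0.45,16.72,10.81,10.31,0.89,0.87,13.29,3.79,5.63,6.46,8.04,5.94,14.99,0.99,0.99
7,55,F,Moderate intimal thickening,48,0.14,0.42,0.03,28.68,4.69,0.9,0.74,3.74,18.54,4.24,5.93,2.46,4.3,12.62,0.97,0.93
8,57,M,"Moderate intimal thickening, moderate calcification",29,0.16,0.46,25.59,15.61,38.81,0.9,0.81,7.52,17.99,15.47,9.39,26.95,20.2,38.77,0.98,0.99
9,59,F,Moderate intimal thickening,64,0.15,0.44,26.45,1.29,31.93,0.57,0.92,3.28,0.09,0.23,9.63,10.23,13.55,18.71,0.91,0.97
10,61,F,Mild intimal thickening,34,0.16,0.46,20.31,1.52,32.04,0.89,0.73,9.96,4.25,14.7,3.36,11.39,3.84,27.58,0.97,0.98
11,63,F,"Moderate intimal thickening, mild calcification, moderate lipid",48,0.18,0.43,10.62,9.85,21.84,0.8,0.88,6.14,11.94,5.64,4.71,11.76,3.44,35.58,0.97,0.96
12,65,M,"Moderate intimal thickening, mild calcification",39,0.17,0.44,14.35,4.58,13.17,0.85,0.9,7.26,11.99,2.26,4.34,7.83,3.22,15.41,0.99,0.98
13,69,M,Moderate intimal thickening,42,0.14,0.39,5.81,19.94,12.21,0.78,0.95,2.8,10.07,0.64,5.66,8.57,8.86,21.61,0.99,0.99
14,70,M,"Moderate intimal thickening, severe calcification",44,0.13,0.47,119.24,86.65,171.23,0.88,0.68,0,90.99,94.75,189.9,34.46,160.19,162.63,0.96,0.97
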