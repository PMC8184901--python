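patient,side,quantity,provenance,value
1,left,mass_g,expert,148
1,left,mass_g,ai,169
1,right,mass_g,expert,148
1,right,mass_g,ai,166
2,left,mass_g,expert,102
2,left,mass_g,ai,93
2,right,mass_g,expert,166
2,right,mass_g,ai,184
3,left,mass_g,expert,254
3,left,mass_g,ai,243
3,right,mass_g,expert,
3,right,mass_g,ai,
4,left,mass_g,expert,147
4,left,mass_g,ai,125
4,right,mass_g,expert,160
4,right,mass_g,ai,137
5,left,mass_g,expert,99
5,left,mass_g,ai,95
5,right,mass_g,expert,122
5,right,mass_g,ai,124
6,left,mass_g,expert,142
6,left,mass_g,ai,138
6,right,mass_g,expert,127
6,right,mass_g,ai,104
7,left,mass_g,expert,107
7,left,mass_g,ai,102
7,right,mass_g,expert,90
7,right,mass_g,ai,90
8,left,mass_g,expert,184
8,left,mass_g,ai,188
8,right,mass_g,expert,178
8,right,mass_g,ai,170
1,left,mean_dose_Gy,expert,1.79
1,left,mean_dose_Gy,ai,1.77
1,right,mean_dose_Gy,expert,1.61
1,right,mean_dose_Gy,ai,1.55
2,left,mean_dose_Gy,expert,1.72
2,left,mean_dose_Gy,ai,1.56
2,right,mean_dose_Gy,expert,1.50
2,right,mean_dose_Gy,ai,1.42
3,left,mean_dose_Gy,expert,1.89
3,left,mean_dose_Gy,ai,1.85
3,right,mean_dose_Gy,expert,
3,right,mean_dose_Gy,ai,
4,left,mean_dose_Gy,expert,1.77
4,left,mean_dose_Gy,ai,1.82
4,right,mean_dose_Gy,expert,1.57
4,right,mean_dose_Gy,ai,1.73
5,left,mean_dose_Gy,expert,2.83
5,left,mean_dose_Gy,ai,2.82
5,right,mean_dose_Gy,expert,2.52
5,right,mean_dose_Gy,ai,2.54
6,left,mean_dose_Gy,expert,3.49
6,left,mean_dose_Gy,ai,3.34
6,right,mean_dose_Gy,expert,3.39
6,right,mean_dose_Gy,ai,3.56
7,left,mean_dose_Gy,expert,2.19
7,left,mean_dose_Gy,ai,1.74
7,right,mean_dose_Gy,expert,2.66
7,right,mean_dose_Gy,ai,1.87
8,left,mean_dose_Gy,expert,2.00
8,left,mean_dose_Gy,ai,2.16
8,right,mean_dose_Gy,expert,2.01
8,right,mean_dose_Gy,ai,2.08
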