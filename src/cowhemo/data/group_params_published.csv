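feature,group,mode,mean,se,n,source
area_S1,2c,geom,0.06,0.006,10,published
area_S1,2d,geom,0.10,0.016,9,published
area_S3,2c,geom,0.12,0.009,10,published
area_S3,2d,geom,0.09,0.005,9,published
area_S6,2c,geom,0.10,0.008,10,published
area_S6,2d,geom,0.07,0.004,9,published
angle_2,2c,geom,67.60,2.663,10,published
angle_2,2d,geom,60.22,2.783,9,published
R_5_6,2c,steady,57.18,4.679,10,published
R_5_6,2d,steady,97.64,15.565,9,published
vmax_S1,2c,steady,15.22,0.919,10,published
vmax_S1,2d,steady,9.98,1.091,9,published
vmax_S13,2c,steady,9.45,1.230,10,published
vmax_S13,2d,steady,17.89,4.230,9,published
vmax_S15,2c,steady,25.96,5.461,10,published
vmax_S15,2d,steady,9.49,1.406,9,published
vmax_S16,2c,steady,15.55,2.790,10,published
vmax_S16,2d,steady,9.05,1.854,9,published
Q_15_16,2c,steady,4.70,0.001,10,published
Q_15_16,2d,steady,2.60,0.001,9,published
vmax_S22,1c,steady,12.67,1.471,7,published
vmax_S22,1d,steady,8.33,0.766,5,published
R_5_6,2c,transient,60.95,5.893,10,published
R_5_6,2d,transient,99.24,14.945,9,published
vmax_S1,2c,transient,14.22,0.649,10,published
vmax_S1,2d,transient,9.59,1.038,9,published
vmax_S13,2c,transient,9.04,1.129,10,published
vmax_S13,2d,transient,16.79,3.880,9,published
vmax_S15,2c,transient,24.77,4.851,10,published
vmax_S15,2d,transient,9.02,1.396,9,published
vmax_S16,2c,transient,15.01,2.456,10,published
vmax_S16,2d,transient,8.84,1.782,9,published
Q_15_16,2c,transient,4.52,0.001,10,published
Q_15_16,2d,transient,2.45,0.0004,9,published
vmax_S22,1c,transient,12.06,1.326,7,published
vmax_S22,1d,transient,8.13,0.666,5,published
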