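engine,n_hidden,rmse,r2
scg,1,2.23,0.95
scg,2,1.81,0.97
scg,3,3.18,0.96
scg,4,1.76,0.96
scg,5,3.17,0.96
scg,6,1.01,0.96
scg,7,1.41,0.95
scg,8,1.02,0.97
scg,9,2.32,0.96
scg,10,0.86,0.98
scg,11,1.76,0.96
scg,12,1.46,0.96
scg,13,1.19,0.97
scg,14,1.14,0.94
scg,15,2.30,0.97
lm,1,1.29,0.93
lm,2,0.83,0.96
lm,3,1.22,0.93
lm,4,0.94,0.96
lm,5,1.35,0.93
lm,6,1.11,0.95
lm,7,2.17,0.98
lm,8,0.74,0.98
lm,9,1.21,0.94
lm,10,1.18,0.95
lm,11,1.10,0.95
lm,12,1.16,0.94
lm,13,1.32,0.92
lm,14,1.00,0.96
lm,15,1.33,0.94
br,1,1.29,0.93
br,2,1.83,0.89
br,3,1.07,0.95
br,4,1.32,0.93
br,5,1.89,0.90
br,6,1.63,0.90
br,7,1.39,0.92
br,8,1.32,0.92
br,9,0.86,0.96
br,10,1.05,0.95
br,11,1.00,0.95
br,12,1.32,0.93
br,13,1.03,0.95
br,14,0.98,0.96
br,15,1.14,0.94
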