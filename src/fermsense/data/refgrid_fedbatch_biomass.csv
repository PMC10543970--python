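engine,n_hidden,rmse,r2
scg,1,0.72,0.99
scg,2,1.05,0.96
scg,3,0.95,1.19
scg,4,1.23,0.98
scg,5,1.06,0.97
scg,6,0.95,0.98
scg,7,1.82,0.95
scg,8,2.14,0.92
scg,9,1.12,0.97
scg,10,1.24,0.97
scg,11,1.19,0.98
scg,12,2.21,0.87
scg,13,1.77,0.96
scg,14,2.14,0.96
scg,15,1.81,0.95
lm,1,0.41,1.00
lm,2,0.84,0.99
lm,3,0.73,0.99
lm,4,0.63,0.99
lm,5,0.79,0.99
lm,6,0.40,0.99
lm,7,0.48,0.99
lm,8,0.45,0.99
lm,9,0.54,0.99
lm,10,0.94,0.99
lm,11,0.68,0.99
lm,12,0.76,0.98
lm,13,0.65,1.00
lm,14,0.60,1.00
lm,15,0.84,0.99
br,1,0.63,-0.15
br,2,0.49,0.82
br,3,0.48,-0.07
br,4,0.80,0.47
br,5,0.41,0.13
br,6,0.79,0.57
br,7,0.89,0.30
br,8,0.89,0.59
br,9,0.89,0.59
br,10,0.84,0.36
br,11,0.72,0.52
br,12,0.66,0.56
br,13,0.61,0.47
br,14,0.65,0.39
br,15,0.67,0.66
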