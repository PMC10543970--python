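engine,n_hidden,rmse,r2
scg,1,0.109,0.77
scg,2,0.086,0.90
scg,3,0.116,0.76
scg,4,0.083,0.89
scg,5,0.098,0.83
scg,6,0.103,0.83
scg,7,0.086,0.86
scg,8,0.091,0.90
scg,9,0.094,0.89
scg,10,0.081,0.90
scg,11,0.083,0.87
scg,12,0.085,0.90
scg,13,0.091,0.86
scg,14,0.103,0.847
scg,15,0.122,0.729
lm,1,0.09,0.75
lm,2,0.13,0.50
lm,3,0.25,0.24
lm,4,0.14,0.46
lm,5,1.50,0.39
lm,6,0.84,0.38
lm,7,0.33,0.04
lm,8,0.44,0.25
lm,9,1.67,0.12
lm,10,0.61,0.21
lm,11,0.88,0.21
lm,12,0.44,0.01
lm,13,0.66,0.34
lm,14,0.66,0.34
lm,15,0.34,0.06
br,1,0.11,0.75
br,2,0.29,0.38
br,3,0.23,0.28
br,4,0.26,0.41
br,5,0.17,0.45
br,6,0.34,0.08
br,7,0.39,0.16
br,8,0.55,0.28
br,9,0.60,0.06
br,10,0.83,0.21
br,11,0.58,0.06
br,12,0.46,0.05
br,13,0.52,0.08
br,14,0.88,0.23
br,15,0.96,0.12
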