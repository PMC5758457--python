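id,age_band,kind,baseline,low,high
c_iui,,cost,2550,1275,3825
c_ivf,,cost,17651,8825,26476
p_low_cs,,probability,0.336,0.269,0.403
p_iui,<35,probability,0.161,0.081,0.242
p_iui,35-37,probability,0.136,0.068,0.204
p_iui,38-40,probability,0.118,0.059,0.177
p_iui,41-42,probability,0.068,0.034,0.102
p_iui,>42,probability,0.035,0.018,0.053
p_tiui,,probability,0.400,0.320,0.480
p_ivf,<35,probability,0.506,0.405,0.607
p_ivf,35-37,probability,0.445,0.356,0.534
p_ivf,38-40,probability,0.320,0.256,0.384
p_ivf,41-42,probability,0.224,0.179,0.269
p_ivf,>42,probability,0.121,0.097,0.145
l_iui,<35,probability,0.559,0.279,0.838
l_iui,35-37,probability,0.495,0.248,0.743
l_iui,38-40,probability,0.462,0.231,0.692
l_iui,41-42,probability,0.400,0.200,0.600
l_iui,>42,probability,0.386,0.193,0.579
l_ivf,<35,probability,0.879,0.854,0.903
l_ivf,35-37,probability,0.829,0.793,0.865
l_ivf,38-40,probability,0.772,0.722,0.822
l_ivf,41-42,probability,0.594,0.500,0.688
l_ivf,>42,probability,0.496,0.324,0.670
n_iui,,count,3,3,3
n_ivf,,count,3,3,3
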