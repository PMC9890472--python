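name	x	y	z
Fp1	-0.026250	0.080791	-0.002966
Fp2	0.026250	0.080791	-0.002966
F3	-0.046326	0.057207	0.042500
F4	0.046326	0.057207	0.042500
C3	-0.061144	-0.000000	0.059046
C4	0.061144	0.000000	0.059046
P3	-0.046326	-0.057207	0.042500
P4	0.046326	-0.057207	0.042500
O1	-0.026250	-0.080791	-0.002966
O2	0.026250	-0.080791	-0.002966
F7	-0.068725	0.049931	-0.002966
F8	0.068725	0.049931	-0.002966
T7	-0.084948	-0.000000	-0.002966
T8	0.084948	0.000000	-0.002966
P7	-0.068725	-0.049931	-0.002966
P8	0.068725	-0.049931	-0.002966
Fz	0.000000	0.061144	0.059046
Cz	0.000000	0.000000	0.085000
Pz	0.000000	-0.061144	0.059046
F1	-0.024392	0.060372	0.054637
F2	0.024392	0.060372	0.054637
FC1	-0.031850	0.031850	0.072084
FC2	0.031850	0.031850	0.072084
C1	-0.033212	-0.000000	0.078243
C2	0.033212	0.000000	0.078243
CP1	-0.031850	-0.031850	0.072084
CP2	0.031850	-0.031850	0.072084
P1	-0.024392	-0.060372	0.054637
P2	0.024392	-0.060372	0.054637
AF3	-0.034531	0.074052	0.023429
AF4	0.034531	0.074052	0.023429
FC3	-0.056932	0.036972	0.051154
FC4	0.056932	0.036972	0.051154
CP3	-0.056175	-0.036480	0.052331
CP4	0.056175	-0.036480	0.052331
PO3	-0.034531	-0.074052	0.023429
PO4	0.034531	-0.074052	0.023429
F5	-0.061964	0.053865	0.022000
F6	0.061964	0.053865	0.022000
FC5	-0.075470	0.028970	0.026266
FC6	0.075470	0.028970	0.026266
C5	-0.079354	-0.000000	0.030461
C6	0.079354	0.000000	0.030461
CP5	-0.075470	-0.028970	0.026266
CP6	0.075470	-0.028970	0.026266
P5	-0.061964	-0.053865	0.022000
P6	0.061964	-0.053865	0.022000
AF7	-0.049931	0.068725	-0.002966
AF8	0.049931	0.068725	-0.002966
FT7	-0.080791	0.026250	-0.002966
FT8	0.080791	0.026250	-0.002966
TP7	-0.080791	-0.026250	-0.002966
TP8	0.080791	-0.026250	-0.002966
PO7	-0.049931	-0.068725	-0.002966
PO8	0.049931	-0.068725	-0.002966
TP9	-0.073266	-0.023805	-0.035923
TP10	0.073266	-0.023805	-0.035923
Fpz	0.000000	0.084948	-0.002966
AFz	0.000000	0.079354	0.030461
FCz	0.000000	0.033212	0.078243
CPz	0.000000	-0.033212	0.078243
POz	0.000000	-0.079354	0.030461
Oz	0.000000	-0.084948	-0.002966
Iz	0.000000	-0.077036	-0.035923
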