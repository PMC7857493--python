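element	radius
C	1.87
N	1.65
O	1.40
S	1.85
P	1.80
H	1.00
F	1.47
CL	1.75
BR	1.85
I	1.98
FE	1.47
CA	1.74
ZN	1.39
MG	1.73
NA	2.27
K	2.75
SE	1.90
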