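unit	length_bp
A	39443
J	3908
K	39470
C	35384
B	39313
D	34472
H	5212
E	27177
G	5443
F	8311
I	2351
N	27635
O	4926
K2	56817
L	42335
M	9760
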