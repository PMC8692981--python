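molecule	A_pct	C_pct	G_pct	T_pct	GC_pct	length_bp
M1	27.88	22.14	22.26	27.72	44.40	169330
M2	27.67	21.68	23.18	27.47	44.86	44455
M3	27.87	22.23	23.06	26.84	45.29	39474
M4	27.76	21.65	22.83	27.76	44.48	32520
M5	27.29	22.43	22.57	27.71	45.00	113793
LS1	27.81	22.34	22.28	27.58	44.62	253259
LS2	27.39	22.52	22.36	27.72	44.88	146313
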