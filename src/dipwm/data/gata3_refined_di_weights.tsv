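# kind=weights
# order=di
# motif_length=6
# cutoff=-3.5
# provenance=published refined GATA-3 di-nucleotide weight matrix (optimized cutoff -3.5)
symbol	1	2	3	4	5
AA	-4.62	-5.66	-6.16	-5.81	-0.16
AC	-4.41	-5.45	-5.94	-5.60	-1.20
AG	0.00	-5.91	-3.39	-6.06	-0.05
AT	-4.14	-5.18	0.00	-5.33	-0.02
CA	-4.70	-4.34	-6.24	-5.89	-4.28
CC	-5.17	-6.22	-6.71	-6.37	-4.76
CG	-0.47	-5.80	-6.29	-5.95	-2.95
CT	-4.84	-5.89	-6.38	-6.04	-4.43
GA	-4.69	0.00	-6.22	-3.38	-4.27
GC	-3.70	-6.14	-6.63	-6.29	-3.29
GG	-2.69	-4.83	-6.72	-6.38	-2.27
GT	-4.44	-4.08	-4.57	-3.54	-4.02
TA	-4.02	-5.06	-5.55	0.00	0.00
TC	-4.69	-5.73	-6.22	-4.48	-4.27
TG	-0.09	-5.75	-6.24	-3.11	-0.06
TT	-4.58	-5.62	-4.72	-1.20	-4.17
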