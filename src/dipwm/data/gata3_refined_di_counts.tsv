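# kind=counts
# order=di
# motif_length=6
# site_count=79
# provenance=published observed di-nucleotide counts of the refined GATA-3 matrix (79 promoter-extracted sites)
symbol	1	2	3	4	5
AA	0	0	0	0	14
AC	0	0	0	0	4
AG	32	0	5	0	20
AT	0	0	72	0	10
CA	0	1	0	0	0
CC	0	0	0	0	0
CG	18	0	0	0	1
CT	0	0	0	0	0
GA	0	76	0	3	0
GC	1	0	0	0	1
GG	3	1	0	0	3
GT	0	1	1	2	0
TA	0	0	0	45	9
TC	0	0	0	1	0
TG	25	0	0	4	17
TT	0	0	1	24	0
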