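# unified oligonucleotide nearest-neighbor parameters, version 1
# step = 5'->3' dinucleotide on the probe strand, paired with its Watson-Crick complement
# dH kcal/mol, dS cal/(mol*K), dG37 kcal/mol
# init_AT / init_GC = per-terminal duplex initiation for an A.T / G.C closing pair
step	dH	dS	dG37
AA	-7.9	-22.2	-1.00
AC	-8.4	-22.4	-1.44
AG	-7.8	-21.0	-1.28
AT	-7.2	-20.4	-0.88
CA	-8.5	-22.7	-1.45
CC	-8.0	-19.9	-1.84
CG	-10.6	-27.2	-2.17
CT	-7.8	-21.0	-1.28
GA	-8.2	-22.2	-1.30
GC	-9.8	-24.4	-2.24
GG	-8.0	-19.9	-1.84
GT	-8.4	-22.4	-1.44
TA	-7.2	-21.3	-0.58
TC	-8.2	-22.2	-1.30
TG	-8.5	-22.7	-1.45
TT	-7.9	-22.2	-1.00
init_AT	2.3	4.1	1.03
init_GC	0.1	-2.8	0.98
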