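# provenance: RNA:RNA Watson-Crick nearest-neighbor parameters, Xia et al. (1998) Biochemistry 37:14719-14735 (1 M NaCl reference).
# stack = 5'->3' top-strand dinucleotide of the duplex; dH kcal/mol,
# dS cal/(mol*K). INIT = duplex initiation; TERM_AU = per terminal A:U pair;
# SYM = self-complementary symmetry correction.
stack	dH	dS
AA	-6.82	-19.0
AC	-11.40	-29.5
AG	-10.48	-27.1
AU	-9.38	-26.7
CA	-10.44	-26.9
CC	-13.39	-32.7
CG	-10.64	-26.7
CU	-10.48	-27.1
GA	-12.44	-32.5
GC	-14.88	-36.9
GG	-13.39	-32.7
GU	-11.40	-29.5
UA	-7.69	-20.5
UC	-12.44	-32.5
UG	-10.44	-26.9
UU	-6.82	-19.0
INIT	3.61	-1.5
TERM_AU	3.72	10.5
SYM	0.00	-1.4
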