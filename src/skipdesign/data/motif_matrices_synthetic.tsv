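# Synthetic SR-protein-like ESE position weight matrices (log-odds vs uniform
# background). These are consensus-derived stand-ins for published ESE matrix
# sets (ESEfinder-class SRSF1/SRSF2/SRSF5/SRSF6 and Human Splice Finder
# libraries), NOT reproductions of them; replace this file with your own
# matrices in the same format for production scans.
# Format: ">name kind threshold" then four rows A/C/G/U of per-position scores.
>SRSF1_like ESE 5.5
A	0.3	1.1	1.1	0.3	1.1	1.1	0.3
C	-1.6	-1.6	-1.6	-1.6	-1.6	-1.6	-1.6
G	1.1	0.3	0.3	1.1	0.3	0.3	1.1
U	-1.6	-1.6	-1.6	-1.6	-1.6	-1.6	-1.6
>SRSF2_like ESE 6.0
A	0.3	0.3	-1.6	-1.6	-1.6	-1.6	-1.6	0.3
C	-1.6	-1.6	1.1	1.1	0.3	1.1	0.3	-1.6
G	1.1	1.1	-1.6	-1.6	-1.6	-1.6	-1.6	1.1
U	-1.6	-1.6	0.3	0.3	1.1	0.3	1.1	-1.6
>SRSF5_like ESE 5.0
A	1.1	-1.6	1.1	0.3	1.1	1.1	0.3
C	-1.6	1.1	-1.6	-1.6	-1.6	-1.6	-1.6
G	0.3	-1.6	0.3	1.1	0.3	0.3	1.1
U	-1.6	0.3	-1.6	-1.6	-1.6	-1.6	-1.6
>SRSF6_like ESE 4.6
A	-1.6	0.3	1.1	1.1	0.3	1.1
C	0.3	-1.6	-1.6	-1.6	-1.6	-1.6
G	-1.6	1.1	0.3	0.3	1.1	0.3
U	1.1	-1.6	-1.6	-1.6	-1.6	-1.6
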