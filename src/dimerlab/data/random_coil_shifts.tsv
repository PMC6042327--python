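residue_type	ca_ppm	cb_ppm	co_ppm
ALA	52.5	19.1	177.8
ARG	56.0	30.9	176.3
ASN	53.1	38.9	175.2
ASP	54.2	41.1	176.3
CYS	58.2	28.0	174.6
GLN	55.7	29.4	176.0
GLU	56.6	29.9	176.6
GLY	45.1		174.9
HIS	55.0	29.0	174.1
ILE	61.1	38.8	176.4
LEU	55.1	42.4	177.6
LYS	56.2	33.1	176.6
MET	55.4	32.9	176.3
PHE	57.7	39.6	175.8
PRO	63.3	32.1	177.3
SER	58.3	63.8	174.6
THR	61.8	69.8	174.7
TRP	57.5	29.6	176.1
TYR	57.9	38.8	175.9
VAL	62.2	32.9	176.3
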