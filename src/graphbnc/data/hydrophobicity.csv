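residue,kyte_doolittle,hopp_woods,eisenberg,janin,engelman_ges
ALA,1.8,-0.5,0.62,0.3,1.6
ARG,-4.5,3.0,-2.53,-1.4,-12.3
ASN,-3.5,0.2,-0.78,-0.5,-4.8
ASP,-3.5,3.0,-0.90,-0.6,-9.2
CYS,2.5,-1.0,0.29,0.9,2.0
GLN,-3.5,0.2,-0.85,-0.7,-4.1
GLU,-3.5,3.0,-0.74,-0.7,-8.2
GLY,-0.4,0.0,0.48,0.3,1.0
HIS,-3.2,-0.5,-0.40,-0.1,-3.0
ILE,4.5,-1.8,1.38,0.7,3.1
LEU,3.8,-1.8,1.06,0.5,2.8
LYS,-3.9,3.0,-1.50,-1.8,-8.8
MET,1.9,-1.3,0.64,0.4,3.4
PHE,2.8,-2.5,1.19,0.5,3.7
PRO,-1.6,0.0,0.12,-0.3,-0.2
SER,-0.8,0.3,-0.18,-0.1,0.6
THR,-0.7,-0.4,-0.05,-0.2,1.2
TRP,-0.9,-3.4,0.81,0.3,1.9
TYR,-1.3,-2.3,0.26,-0.4,-0.7
VAL,4.2,-1.5,1.08,0.6,2.6
SEC,2.5,-1.0,0.29,0.9,2.0
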