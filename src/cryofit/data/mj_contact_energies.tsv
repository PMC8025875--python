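# Like-pair statistical contact energies (RT units) of the
# Miyazawa-Jernigan type, one value per residue type.  Pair energies are
# derived by the one-body (Li-Tang-Wingreen) factorization
# e_ij = -sqrt(e_ii * e_jj); only the relative magnitudes matter because
# contact well depths are renormalized to a configurable mean.
ALA	-2.72
ARG	-1.55
ASN	-1.68
ASP	-1.21
CYS	-5.44
GLN	-1.54
GLU	-0.91
GLY	-2.24
HIS	-3.05
ILE	-6.54
LEU	-7.04
LYS	-0.25
MET	-5.46
PHE	-7.26
PRO	-1.89
SER	-1.67
THR	-2.12
TRP	-5.06
TYR	-4.17
VAL	-5.52
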