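residue	atom	flags	ring
*	N	donor	.
*	O	acceptor	.
*	OXT	acceptor,anion	.
PRO	N	none	.
SER	OG	donor,acceptor	.
THR	OG1	donor,acceptor	.
CYS	SG	donor	.
MET	SD	acceptor	.
ASN	OD1	acceptor	.
ASN	ND2	donor	.
GLN	OE1	acceptor	.
GLN	NE2	donor	.
ASP	OD1	acceptor,anion	.
ASP	OD2	acceptor,anion	.
GLU	OE1	acceptor,anion	.
GLU	OE2	acceptor,anion	.
LYS	NZ	donor,cation	.
ARG	NE	donor,cation	.
ARG	NH1	donor,cation	.
ARG	NH2	donor,cation	.
HIS	ND1	donor,acceptor	1
HIS	NE2	donor,acceptor	1
HIS	CG	none	1
HIS	CD2	none	1
HIS	CE1	none	1
TRP	NE1	donor	1
TRP	CG	none	1
TRP	CD1	none	1
TRP	CD2	none	1,2
TRP	CE2	none	1,2
TRP	CE3	none	2
TRP	CZ2	none	2
TRP	CZ3	none	2
TRP	CH2	none	2
PHE	CG	none	1
PHE	CD1	none	1
PHE	CD2	none	1
PHE	CE1	none	1
PHE	CE2	none	1
PHE	CZ	none	1
TYR	OH	donor,acceptor	.
TYR	CG	none	1
TYR	CD1	none	1
TYR	CD2	none	1
TYR	CE1	none	1
TYR	CE2	none	1
TYR	CZ	none	1
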