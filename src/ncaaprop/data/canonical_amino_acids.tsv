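code	one_letter	name	smiles
ALA	A	ALANINE	C[C@H](N)C(O)=O
ARG	R	ARGININE	N[C@@H](CCCNC(N)=[NH2+])C(O)=O
ASN	N	ASPARAGINE	NC(=O)C[C@H](N)C(O)=O
ASP	D	ASPARTIC ACID	N[C@@H](CC(O)=O)C(O)=O
CYS	C	CYSTEINE	N[C@@H](CS)C(O)=O
GLN	Q	GLUTAMINE	NC(=O)CC[C@H](N)C(O)=O
GLU	E	GLUTAMIC ACID	N[C@@H](CCC(O)=O)C(O)=O
GLY	G	GLYCINE	NCC(O)=O
HIS	H	HISTIDINE	N[C@@H](Cc1c[nH]c[nH+]1)C(O)=O
ILE	I	ISOLEUCINE	CC[C@H](C)[C@H](N)C(O)=O
LEU	L	LEUCINE	CC(C)C[C@H](N)C(O)=O
LYS	K	LYSINE	N[C@@H](CCCC[NH3+])C(O)=O
MET	M	METHIONINE	CSCC[C@H](N)C(O)=O
PHE	F	PHENYLALANINE	N[C@@H](Cc1ccccc1)C(O)=O
PRO	P	PROLINE	C1C[C@H](NC1)C(O)=O
SER	S	SERINE	N[C@@H](CO)C(O)=O
THR	T	THREONINE	C[C@@H](O)[C@H](N)C(O)=O
TRP	W	TRYPTOPHAN	N[C@@H](Cc1c[nH]c2ccccc12)C(O)=O
TYR	Y	TYROSINE	N[C@@H](Cc1ccc(O)cc1)C(O)=O
VAL	V	VALINE	CC(C)[C@H](N)C(O)=O
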