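code	name	smiles	number	percent
MLY	N-DIMETHYL-LYSINE	CN(C)CCCC[C@H](N)C(O)=O	5324	20.151
HYP	4-HYDROXYPROLINE	O[C@H]1CN[C@@H](C1)C(O)=O	2264	8.569
NAG	2-ACETAMIDO-2-DEOXY-BETA-D-GLUCOPYRANOSE	CC(=O)N[C@H]1[C@H](O)O[C@H](CO)[C@@H](O)[C@@H]1O	983	3.721
CSO	S-HYDROXYCYSTEINE	N[C@@H](CSO)C(O)=O	890	3.369
CRO	{2-[(1R,2R)-1-AMINO-2-HYDROXYPROPYL]-4-(4-HYDROXYBENZYLIDENE)-5-OXO-4,5-DIHYDRO-1H-IMIDAZOL-1-YL}ACETIC ACID	C[C@@H](O)[C@H](N)C1=N\C(=C/c2ccc(O)cc2)C(=O)N1CC(O)=O	886	3.354
KCX	LYSINE NZ-CARBOXYLIC ACID	N[C@@H](CCCCNC(O)=O)C(O)=O	877	3.319
PCA	PYROGLUTAMIC ACID	OC(=O)[C@@H]1CCC(=O)N1	783	2.964
CME	S,S-(2-HYDROXYETHYL)THIOCYSTEINE	N[C@@H](CSSCCO)C(O)=O	679	2.570
CSD	3-SULFINOALANINE	N[C@@H](C[S](O)=O)C(O)=O	617	2.335
NRQ	{(4Z)-4-(4-HYDROXYBENZYLIDENE)-2-[3-(METHYLTHIO)PROPANIMIDOYL]-5-OXO-4,5-DIHYDRO-1H-IMIDAZOL-1-YL}ACETIC ACID	CSCCC(=N)C1=N\C(=C/c2ccc(O)cc2)C(=O)N1CC(O)=O	604	2.286
CR2	{(4Z)-2-(AMINOMETHYL)-4-[(4-HYDROXYPHENYL)METHYLIDENE]-5-OXO-4,5-DIHYDRO-1H-IMIDAZOL-1-YL}ACETIC ACID	NCC1=N\C(=C/c2ccc(O)cc2)C(=O)N1CC(O)=O	521	1.972
CGU	GAMMA-CARBOXY-GLUTAMIC ACID	N[C@@H](CC(C(O)=O)C(O)=O)C(O)=O	507	1.919
GYC	[(4Z)-2-[(1R)-1-AMINO-2-MERCAPTOETHYL]-4-(4-HYDROXYBENZYLIDENE)-5-OXO-4,5-DIHYDRO-1H-IMIDAZOL-1-YL]ACETIC ACID	N[C@@H](CS)C1=N\C(=C/c2ccc(O)cc2)C(=O)N1CC(O)=O	396	1.499
CRQ	[2-(3-CARBAMOYL-1-IMINO-PROPYL)-4-(4-HYDROXY-BENZYLIDENE)-5-OXO-4,5-DIHYDRO-IMIDAZOL-1-YL]-ACETIC ACID	NC(=O)CCC(=N)C1=N\C(=C/c2ccc(O)cc2)C(=O)N1CC(O)=O	381	1.442
MDO	{2-[(1S)-1-AMINOETHYL]-4-METHYLIDENE-5-OXO-4,5-DIHYDRO-1H-IMIDAZOL-1-YL}ACETIC ACID	C[C@H](N)C1=NC(=C)C(=O)N1CC(O)=O	356	1.347
OCS	CYSTEINESULFONIC ACID	N[C@@H](C[S](O)(=O)=O)C(O)=O	352	1.332
FME	N-FORMYLMETHIONINE	CSCC[C@H](NC=O)C(O)=O	300	1.136
ORN	L-ORNITHINE	NCCC[C@H](N)C(O)=O	299	1.132
ABA	ALPHA-AMINOBUTYRIC ACID	CC[C@H](N)C(O)=O	284	1.075
CR8	2-[1-AMINO-2-(1H-IMIDAZOL-5-YL)ETHYL]-1-(CARBOXYMETHYL)-4-[(4-OXOCYCLOHEXA-2,5-DIEN-1-YLIDENE)METHYL]-1H-IMIDAZOL-5-OLATE	N[C@@H](Cc1[nH]cnc1)c2nc(C=C3C=CC(=O)C=C3)c([O-])n2CC(O)=O	279	1.056
TYS	O-SULFO-L-TYROSINE	N[C@@H](Cc1ccc(O[S](O)(=O)=O)cc1)C(O)=O	276	1.045
SMC	S-METHYLCYSTEINE	CSC[C@H](N)C(O)=O	258	0.977
M3L	N-TRIMETHYLLYSINE	C[N+](C)(C)CCCC[C@H](N)C(O)=O	254	0.961
ALY	N(6)-ACETYLLYSINE	CC(=O)NCCCC[C@H](N)C(O)=O	239	0.905
GYS	[(4Z)-2-(1-AMINO-2-HYDROXYETHYL)-4-(4-HYDROXYBENZYLIDENE)-5-OXO-4,5-DIHYDRO-1H-IMIDAZOL-1-YL]ACETIC ACID	N[C@@H](CO)C1=N\C(=C/c2ccc(O)cc2)C(=O)N1CC(O)=O	225	0.852
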