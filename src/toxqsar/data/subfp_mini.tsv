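# Curated SubFP-style substructure dictionary (in-house subset).
# Columns: index <TAB> SMARTS-or-countrule <TAB> description
# Includes the classical alert bits (trifluoromethyl, alkylfluoride,
# hetero N basic H, heterocyclic) plus generic functional-group bits.
0	[FX1][CX4;!$([H0][Cl,Br,I]);!$([F][C]([F])([F])[F])]([FX1])([FX1])	Trifluoromethyl
1	[FX1][CX4]	Alkylfluoride
2	[nX3H1+0]	Hetero N basic H
3	[!#6;!R0]	Heterocyclic
4	[FX1]c	Arylfluoride
5	[ClX1][#6]	Chloride
6	[BrX1][#6]	Bromide
7	[IX1][#6]	Iodide
8	[NX3H2][CX4]	Primary aliphatic amine
9	[NX3H1]([CX4])[CX4]	Secondary aliphatic amine
10	[NX3]([CX4])([CX4])[CX4]	Tertiary aliphatic amine
11	c[NX3H2]	Primary aromatic amine
12	[OX2H][CX4]	Aliphatic hydroxyl
13	c[OX2H1]	Phenol
14	[CX4][OX2][CX4]	Dialkyl ether
15	[CX3H1]=O	Aldehyde
16	[#6][CX3](=O)[#6]	Ketone
17	[CX3](=O)[OX2H1]	Carboxylic acid
18	[CX3](=O)[OX2][#6]	Ester
19	[NX3][CX3]=[OX1]	Amide
20	[CX2]#[NX1]	Nitrile
21	[$([NX3](=O)=O),$([NX3+](=O)[O-])]	Nitro
22	[CX3]=[NX2]	Imine
23	[NX2]=[NX2]	Azo
24	[SX2H]	Thiol
25	[#6][SX2][#6]	Thioether
26	[SX4](=[OX1])(=[OX1])[NX3]	Sulfonamide
27	[#6][SX4](=[OX1])(=[OX1])[#6]	Sulfone
28	[PX4](=[OX1])([OX2])([OX2])	Phosphate ester
29	[PX4](=[SX1])	Thiophosphate
30	c1ccccc1	Benzene ring
31	[nX2r6]	Pyridine-type aromatic N
32	[CX3]=[CX3]	Alkene
33	[CX2]#[CX2]	Alkyne
34	[F,Cl,Br,I]	Any halogen
35	[NX3][CX3](=[OX1])[NX3]	Urea
36	[NX3][CX3](=[OX1])[OX2]	Carbamate
37	[NX3][CX3](=[NX2])[NX3]	Guanidine
38	[CX4H3]	Methyl
39	[NX4+]	Quaternary N
40	[n]	Aromatic N
41	[o]	Aromatic O
42	[s]	Aromatic S
43	[OX2H]	Any hydroxyl
44	[#8]=[#6]	Carbonyl any
45	[R2]	Ring fusion atom
46	[CX4F2]	Geminal difluoride
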