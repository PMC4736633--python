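# Curated PubChem-style dictionary (in-house subset).
# Columns: index <TAB> SMARTS-or-countrule <TAB> description
# Element count-rule bits use the syntax ">=<n> <El>"; SMARTS bits are
# RDKit analogues of the named atom-neighbourhood patterns.
0	>=4 C	C count >= 4
1	>=8 C	C count >= 8
2	>=16 C	C count >= 16
3	>=32 C	C count >= 32
4	>=1 N	N count >= 1
5	>=2 N	N count >= 2
6	>=4 N	N count >= 4
7	>=1 O	O count >= 1
8	>=2 O	O count >= 2
9	>=4 O	O count >= 4
10	>=8 O	O count >= 8
11	>=1 F	F count >= 1
12	>=2 F	F count >= 2
13	>=4 F	F count >= 4
14	>=1 Cl	Cl count >= 1
15	>=2 Cl	Cl count >= 2
16	>=1 Br	Br count >= 1
17	>=1 I	I count >= 1
18	>=1 S	S count >= 1
19	>=2 S	S count >= 2
20	>=1 P	P count >= 1
21	[#7;H1](:[#6]):[#6]	Aromatic C-NH-C bond
22	[#6](~[#6])(:[#7]):[#7]	Aromatic diazacyclo C with C substituent
23	[#7]c1c([#7])cccc1	Ortho aryl nitrogen
24	[#7]C1C([#7])CCCC1	Ortho alicyclic nitrogen
25	[#6]:[#6]:[#7;!H0]	Aromatic C-C-NH bond
26	[#6](-[#6])=[#7]	N-ethylimino neighbourhood
27	[#6]=[#7]	Carbon-nitrogen double bond
28	[#6]-[#7]	Carbon-nitrogen single bond
29	[#6]-[#8]	Carbon-oxygen single bond
30	[#6]=[#8]	Carbon-oxygen double bond
31	[#6]-[#16]	Carbon-sulfur single bond
32	[#6]-[#17]	Carbon-chlorine bond
33	[#6]-[#9]	Carbon-fluorine bond
34	[#6]#[#7]	Carbon-nitrogen triple bond
35	[#7]-[#7]	Nitrogen-nitrogen single bond
36	[#7]-[#8]	Nitrogen-oxygen single bond
37	[#7]=[#8]	Nitrogen-oxygen double bond
38	[#8]-[#15]	Oxygen-phosphorus bond
39	[#8]=[#16]	Oxygen-sulfur double bond
40	[#6]=[#6]	Carbon-carbon double bond
41	[#6]#[#6]	Carbon-carbon triple bond
42	c1ccccc1	Benzene ring system
43	c1ccncc1	Pyridine ring system
44	C1CCCCC1	Cyclohexane ring system
45	C1CCCC1	Cyclopentane ring system
46	[R]	Any ring atom
47	[R;!c;!C]	Ring heteroatom
48	[cH0]	Substituted aromatic carbon
49	[#7;R]	Ring nitrogen
50	[#8;R]	Ring oxygen
51	[#16;R]	Ring sulfur
52	[#6;X4](~[#6])(~[#6])~[#6]	Branched sp3 carbon
53	[#7](~[#6])(~[#6])~[#6]	Trisubstituted nitrogen
54	[#8;H1]	Hydroxyl hydrogen donor
55	[#7;H2]	Primary amine neighbourhood
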