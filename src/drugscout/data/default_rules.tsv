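name	phase	reactant_pattern	transformation	max_applications
ester_hydrolysis	I	[CX3](=[OX1])[OX2][CX4]	[C:1](=[O:2])[O:3][CX4:4]>>[C:1](=[O:2])[O:3].[C:4]O	1
amide_hydrolysis	I	[CX3](=[OX1])[NX3;!$(N=*)]	[C:1](=[O:2])[NX3;!$(N=*):3]>>[C:1](=[O:2])O.[N:3]	1
aromatic_hydroxylation	I	[cH]	[cH:1]>>[c:1]O	1
O_demethylation	I	[#6;!$(C=O)][OX2][CH3]	[#6;!$(C=O):1][OX2:2][CH3]>>[#6:1][OX2:2]	1
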