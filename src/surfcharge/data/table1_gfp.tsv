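residue	exposure	secondary_structure	salt_bridge_partners	hbond_partners
K3	Exposed	Loop		
K26	Exposed	β-strand 2	D21	D21
K41	Exposed	β-strand 3		D36
K45	Exposed	β-strand 3	E213;D210	E32;E213
K52	Exposed	Loop		
K79	Exposed	Loop		Y74;H81
K85	Buried	Helix	D82	C70;S72;D82
K101	Exposed	Loop	D102	D102;Q177;L178
K107	Exposed	β-strand 5		N105;K126
K113	Exposed	β-strand 5	E111;E115	E115;V120
K126	Exposed	β-strand 6	D21	D21;G127
K131	Exposed	Loop		D102;D103;D133;D134
K140	Exposed	Loop		N135;E172
K156	Exposed	Loop		N159
K158	Exposed	Loop	D155	D155
K162	Exposed	β-strand 8		M153
K166	Exposed	β-strand 8		
K209	Exposed	Loop		H217
K214	Exposed	Loop		E213
K238	Exposed	Loop		
R73	Exposed	Loop		T38;V224;A226
R96	Buried	β-strand 4		T62;Y66;T108;Q183
R109	Exposed	β-strand 5	E111	E111;E124
R122	Exposed	β-strand 6	E115;E17	E17;E111;E115
R168	Exposed	β-strand 8		N146;H148
R215	Exposed	Loop	E213	E213;H217
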