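residue	exposure	secondary_structure	salt_bridge_partners	hbond_partners
K3	Exposed	Loop		
K26	Exposed	β-strand 2	D21	D21;G24
K41	Exposed	β-strand 3		D36;T43
K45	Exposed	β-strand 3	E213;D210	E32;E213;D210
K52	Exposed	Loop		
K79	Exposed	Loop	E5	E5;P75
K101	Exposed	Loop	D102	D102;Q177;L178
K107	Exposed	β-strand 5		N105;K126
K113	Exposed	β-strand 5	E111;E115	E111;V120
K126	Exposed	β-strand 6	D21	D21
K131	Exposed	Loop	D103	D102;D103;D134
K140	Exposed	Loop		D133;G134;N135
K156	Exposed	Loop		
K158	Exposed	Loop	D155	D155;Q184
K162	Exposed	β-strand 8		M153
K166	Exposed	β-strand 8	D180	D180
K209	Exposed	Loop		Y143;H217
K214	Exposed	Loop		N212
K238	Exposed	Loop		
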