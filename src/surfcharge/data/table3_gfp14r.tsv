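residue	exposure	secondary_structure	salt_bridge_partners	hbond_partners
R3	Exposed	Loop	E6*	E6*
R26	Exposed	β-strand 2	D21	D21
K41	Exposed	β-strand 3	D36*	D36
K45	Exposed	β-strand 3	E213;D210	E32;D210;E213
R52	Exposed	Loop	D216*	T50*;D216*
R79	Exposed	Loop	E5;D76*	E5;Y74*;P75;D76*
R101	Exposed	Loop	D102	D103*;Q177;L178
K107	Exposed	β-strand 5		N105;K126
K113	Exposed	β-strand 5	E111;E115	E111;E115*;V120
K126	Exposed	β-strand 6	D21	D21;G127*
R131	Exposed	Loop	D133*	D102;D103;D134
R140	Exposed	Loop	D173*	D133;G134;N135;E172*;D173*
R156	Exposed	Loop		N159*
R158	Exposed	Loop		D155;Q157*
R162	Exposed	β-strand 8		M153;N164*
R166	Exposed	β-strand 8	D180	D180
R209	Exposed	Loop	D216*	D216*;H217
R214	Exposed	Loop		E213*
R238	Exposed	Loop		
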