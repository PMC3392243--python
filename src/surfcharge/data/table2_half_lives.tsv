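condition	variant	t_half_min	stderr_min
1% SDS	GFP_con	37.44	2.27
1% SDS	GFP14R	166.79	3.98
1% SDBS	GFP_con	27.04	1.24
1% SDBS	GFP14R	78.73	9.2
1% CTAB	GFP_con	22.18	1.2
1% CTAB	GFP14R	31.84	1.7
1% DTAC	GFP_con	3.83	0.32
1% DTAC	GFP14R	6.45	0.3
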