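cm_subcategory	condition	value
S065		0
S065	loc_gt24h_return	5
S065	loc_gt24h_no_return	6
S000		X
S021		X
S122		X
S005		X
S024		X
S070		X
S202		X
S222		X
S2205		X
S224		X
S270		X
S260		X
S250		X
S301		X
S318		X
S360		X
S370		X
S361		X
S350		X
S400		X
S423		X
S525		X
S822		X
S720		X
S781		X
S772		X
T221		X
T202		X
T213		X
T314		X
T318		X
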