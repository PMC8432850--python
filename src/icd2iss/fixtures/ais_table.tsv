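cm_prefix	severities	region
S000	1	1
S021	3	1
S122	2	1
S065	4	1
S065X6	5	1
S099	9	1
S005	1	2
S024	2	2
S070	3	2
S202	1	3
S222	2	3
S2205	2	3
S224	3	3
S270	3	3
S272	3,4	3
S260	4	3
S250	5	3
S301	1	4
S318	2	4
S360	3	4
S370	3	4
S361	4	4
S350	5	4
S400	1	5
S423	2	5
S525	2	5
S822	2	5
S720	3	5
S781	4	5
S772	5	5
T221	1	6
T202	2	6
T213	3	6
T314	4	6
T318	5	6
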