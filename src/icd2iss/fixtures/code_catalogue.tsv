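gm_codes	region	severity
S00.0	1	1
S12.2	1	2
S02.1	1	3
S06.5	1	4
S06.5|S06.73!	1	5
S00.5	2	1
S02.4	2	2
S07.0	2	3
S20.2	3	1
S22.2	3	2
S22.03	3	2
S22.4	3	3
S27.0	3	3
S26.0	3	4
S25.0	3	5
S30.1	4	1
S31.8	4	2
S36.0	4	3
S37.0	4	3
S36.1	4	4
S35.0	4	5
S40.0	5	1
S42.3	5	2
S52.5	5	2
S82.2	5	2
S72.0	5	3
S78.1	5	4
S77.2	5	5
T22.1	6	1
T20.2	6	2
T21.3	6	3
T31.4	6	4
T31.8	6	5
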