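gm_pattern	tag
S067	loc_unspecified
S0670	loc_lt30min
S0671	loc_30min_24h
S0672	loc_gt24h_return
S0673	loc_gt24h_no_return
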