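gm_pattern	cm_target	note
S2203	S2205	GM S22.03 (fracture of fifth/sixth thoracic vertebra) corresponds to CM S22.05, not CM S22.03 (third thoracic vertebra)
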