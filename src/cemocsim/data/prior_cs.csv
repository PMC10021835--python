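prior_cs_count,p_previa,p_accreta,p_elective_repeat
0,0.0006,0.0004,0.0
1,0.0013,0.0012,0.60
2,0.0022,0.0025,0.85
3,0.0040,0.0060,0.95
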