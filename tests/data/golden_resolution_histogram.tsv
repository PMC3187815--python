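threshold	n_queries
99.0	12
85.0	11
80.0	1
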