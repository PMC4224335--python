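# Published pi0 estimates accompanying the q-value columns
table	method	pi0
table2	smoother	0.227
table2	bootstrap	0.208
table3	smoother	0.275
table3	bootstrap	0.260
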