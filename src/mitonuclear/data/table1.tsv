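# mtDNA haplogroup-cluster distribution in the T2DM patient and control groups
cluster	n_cases	n_controls
HV	394	145
UK	431	128
JT	163	43
IW	130	43
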