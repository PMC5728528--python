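method	level	pct_success	n_success	n_total
morphological	family	100.0	22	22
morphological	genus	59.1	13	22
morphological	species	54.5	12	22
standard_barcoding	family	100.0	22	22
standard_barcoding	genus	86.4	19	22
standard_barcoding	species	63.6	14	22
metabarcoding	family	95.5	21	22
metabarcoding	genus	81.8	18	22
metabarcoding	species	54.5	12	22
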