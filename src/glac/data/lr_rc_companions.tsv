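child_class	restored	lpr
0.0-0.1	6184	0
0.1-0.2	54	0
0.8-0.9	0	14
0.9-0.99	0	1395
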