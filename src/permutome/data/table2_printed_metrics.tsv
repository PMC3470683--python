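metric	control	N	Pi	S	K	NPKS	PK	NS	PN	PS
ol_ratio	1.35	1.38	1.34	1.80	1.80	1.76	3.31	1.26	1.29	1.59
percent_unsaturated	82.7	82.6	82.8	83.2	83.8	84.0	82.4	82.0	82.4	83.6
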