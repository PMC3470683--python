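code	control	N	Pi	S	K	NPKS	PK	NS	PN	PS
C16:0	9.7	9.5	9.6	8.6	8.7	8.6	8.3	9.8	10.0	8.7
C16:1	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1
C18:0	2.2	2.2	2.1	2.5	2.7	2.2	3.3	2.1	2.2	2.2
C18:1	46.4	46.7	46.3	52.3	52.8	52.1	62.3	44.5	45.4	50.1
C18:2	34.4	33.9	34.5	28.9	29.2	29.6	18.8	25.2	35.0	31.4
C18:3	<0.1	<0.1	0.1	0.1	<0.1	0.1	<0.1	0.1	0.1	0.1
C20:0	1.3	1.3	1.2	1.3	1.3	1.1	1.5	1.2	1.2	1.2
C20:1	1.7	1.8	1.7	1.7	1.6	1.9	1.7	1.9	1.7	1.8
C22:0	2.8	3.0	2.7	2.8	2.4	2.7	2.6	3.3	2.8	2.8
C22:1	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1	0.1
C24:0	1.4	1.5	1.4	1.4	1.1	1.4	1.3	1.7	1.4	1.4
oil_wt	44.5	42.6	42.0	41.5	41.7	37.9	31.8	44.9	44.0	43.6
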