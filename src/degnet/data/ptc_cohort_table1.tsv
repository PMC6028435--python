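patient_id	gender	age	tumor_diameter_cm	t	n	m	stage
1	female	41	1.00	1	1	0	1
2	female	39	1.30	1	1	0	1
3	female	37	2.00	1	1	0	1
4	female	38	1.40	1	1	0	1
5	female	57	1.20	1	0	0	1
6	female	45	0.80	1	0	0	1
7	female	41	1.50	1	0	0	1
8	female	42	2.00	1	1	0	1
9	female	29	1.50	1	1	0	1
10	female	42	1.20	1	0	0	1
11	female	47	0.80	1	0	0	1
12	female	54	0.90	1	0	0	1
13	female	61	1.80	1	0	0	1
14	female	26	1.20	1	0	0	1
15	female	49	0.70	1	0	0	1
16	female	37	2.00	4	1	0	1
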