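pair_id	age_primary	age_recurrent	sex	localization	margin_primary	margin_recurrent	time_to_recurrence_years	dmr_count
1	64	68	female	upper leg	R1	R1	3.7	32854
2	78	79	male	retroperitoneal	R1	R2	1.9	2430
3	58	69	female	upper leg	R1	R1	10.6	4410
4	50	59	male	upper leg	Rx	R2	8.3	1061
5	62	67	male	axilla	R0	Rx	5.3	1191
6	31	39	female	upper leg	R1	R0	8.5	2732
8	60	61	male	lower leg	Rx	Rx	1.0	724
9	38	40	female	upper leg	R1	R1	2.1	675
10	68	69	female	mediastinum	R0	R1	1.3	1747
11	52	54	female	retroperitoneal	Rx	Rx	2.6	1028
13	50	58	female	retroperitoneal	R1	R1	8.1	3659
14	64	64	male	upper leg	R0	R1	0.6	636
15	55	57	female	retroperitoneal	R1	R1	2.0	1920
16	48	48	male	lower leg	R1	R1	0.4	473
17	70	70	male	esophagus	R2	R2	0.1	586
19	43	48	male	upper leg	R1	R1	4.7	7644
20	64	70	male	upper leg	R1	R1	6.5	21585
21	52	56	male	retroperitoneal	R0	R0	3.5	1481
22	59	63	female	retroperitoneal	Rx	R1	4.2	314
23	47	63	male	upper leg	R1	R0	16.6	1119
24	76	79	female	upper leg	R1	R0	3.0	372
25	49	53	female	upper leg	Rx	R1	3.9	482
26	50	53	female	retroperitoneal	Rx	Rx	2.1	2513
27	60	61	male	retroperitoneal	Rx	R1	1.5	1377
28	71	77	female	upper leg	R0	R1	6.1	1910
29	60	74	male	trunk	Rx	R1	13.8	2819
30	61	66	female	upper leg	R1	R2	4.6	294
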