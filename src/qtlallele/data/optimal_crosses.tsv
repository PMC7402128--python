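cross	role	accession	eco_region	mpw	mph	wav	mpw_pos	mpw_neg	mph_pos	mph_neg
1	P1	N25340	II	1.223	1.439	1.327	35	40	35	29
1	P2	N25258	I	1.411	1.712	1.556	41	34	37	27
1	progeny			2.392	2.552	2.469
2	P1	N25340	II	1.223	1.439	1.327	35	40	35	29
2	P2	N23640	IV	1.273	0.808	1.048	36	39	37	27
2	progeny			2.385	2.664	2.520
3	P1	N07686	IV	1.131	0.561	0.856	34	41	36	28
3	P2	N25340	II	1.223	1.439	1.327	35	40	35	29
3	progeny			2.330	2.762	2.539
4	P1	N25340	II	1.223	1.439	1.327	35	40	35	29
4	P2	N21175	III	1.071	1.168	1.118	36	22	35	29
4	progeny			2.194	2.715	2.446
5	P1	N25340	II	1.223	1.439	1.327	35	40	35	29
5	P2	N04650	IV	0.988	0.110	0.564	36	39	34	30
5	progeny			2.164	2.244	2.203
6	P1	N25148	II	0.708	0.084	0.407	35	39	33	31
6	P2	N25340	II	1.223	1.439	1.327	35	40	35	29
6	progeny			2.146	2.339	2.239
7	P1	N25340	II	1.223	1.439	1.327	35	40	35	29
7	P2	N25321	I	0.645	0.059	0.362	40	35	36	28
7	progeny			2.143	2.347	2.242
8	P1	N24359	VI	0.716	0.477	0.601	34	41	35	29
8	P2	N25340	II	1.223	1.439	1.327	35	40	35	29
8	progeny			2.140	2.417	2.274
9	P1	N25340	II	1.223	1.439	1.327	35	40	35	29
9	P2	N24595	I	0.818	0.321	0.578	37	38	33	31
9	progeny			2.126	2.272	2.197
10	P1	N25340	II	1.223	1.439	1.327	35	40	35	29
10	P2	N24614	III	1.005	1.668	1.325	36	39	37	27
10	progeny			2.107	3.135	2.604
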