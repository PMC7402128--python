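qtl	marker	n_alleles	neg_log10_p	r2_percent	shared
MPW1.1	Gm01_149527	2	11.9	1.0	0
MPW1.2	Gm01_3646943	2	3.2	0.2	0
MPW2.1	Gm02_BLOCK81	7	5.9	0.8	0
MPW2.2	Gm02_14594196	2	11.3	1.0	0
MPW2.3	Gm02_29143788	2	6.9	0.6	0
MPW2.4	Gm02_BLOCK579	5	14.4	1.5	0
MPW3.1	Gm03_326463	2	5.3	0.4	0
MPW3.2	Gm03_BLOCK11	2	7.2	0.6	0
MPW3.3	Gm03_993540	2	13.8	1.2	0
MPW3.4	Gm03_BLOCK283	9	12.5	1.6	0
MPW4.1	Gm04_10567695	2	9.5	0.8	0
MPW4.2	Gm04_BLOCK295	5	19.3	2.0	0
MPW5.1	Gm05_18374832	2	3.5	0.3	1
MPW5.2	Gm05_20554448	2	4.6	0.4	0
MPW5.3	Gm05_33077723	2	2.6	0.2	0
MPW6.1	Gm06_BLOCK201	4	14.9	1.5	0
MPW6.2	Gm06_BLOCK264	2	5.0	0.4	0
MPW6.3	Gm06_BLOCK401	6	4.1	0.5	0
MPW6.4	Gm06_BLOCK522	5	7.3	0.8	0
MPW6.5	Gm06_BLOCK576	3	13.3	1.3	1
MPW7.1	Gm07_3177189	2	8.6	0.7	0
MPW7.2	Gm07_BLOCK229	6	7.5	0.8	0
MPW7.3	Gm07_BLOCK302	4	2.8	0.3	0
MPW7.4	Gm07_BLOCK373	3	3.5	0.3	0
MPW8.1	Gm08_BLOCK49	3	2.8	0.2	0
MPW8.2	Gm08_BLOCK71	4	4.7	0.5	0
MPW8.3	Gm08_11056573	2	2.5	0.2	0
MPW8.4	Gm08_BLOCK165	2	6.2	0.5	0
MPW8.5	Gm08_BLOCK209	2	9.1	0.8	0
MPW8.6	Gm08_BLOCK466	9	4.3	0.7	1
MPW8.7	Gm08_BLOCK527	3	7.7	0.7	0
MPW9.1	Gm09_963514	2	9.6	0.8	0
MPW9.2	Gm09_2378279	2	11.4	1.0	0
MPW9.3	Gm09_BLOCK115	7	7.0	0.9	0
MPW9.4	Gm09_BLOCK142	4	7.0	0.7	0
MPW9.5	Gm09_35353845	2	8.5	0.7	0
MPW9.6	Gm09_36608762	2	3.1	0.2	0
MPW10.1	Gm10_BLOCK71	5	16.8	1.8	0
MPW10.2	Gm10_BLOCK96	3	5.1	0.5	0
MPW10.3	Gm10_BLOCK159	7	23.0	2.5	0
MPW10.4	Gm10_BLOCK229	8	21.5	2.4	0
MPW10.5	Gm10_38212261	2	8.1	0.7	0
MPW11.1	Gm11_BLOCK126	4	4.1	0.4	0
MPW11.2	Gm11_17784579	2	3.3	0.3	0
MPW11.3	Gm11_BLOCK216	5	6.5	0.7	0
MPW11.4	Gm11_BLOCK241	3	3.6	0.3	0
MPW11.5	Gm11_26892595	2	8.4	0.7	0
MPW12.1	Gm12_8508827	2	3.5	0.3	0
MPW12.2	Gm12_BLOCK254	5	3.3	0.4	0
MPW12.3	Gm12_BLOCK402	3	4.9	0.5	0
MPW12.4	Gm12_BLOCK429	3	8.4	0.8	0
MPW13.1	Gm13_2179313	2	2.5	0.2	0
MPW13.2	Gm13_BLOCK338	6	33.0	3.5	0
MPW13.3	Gm13_BLOCK486	4	13.4	1.3	0
MPW14.1	Gm14_39515432	2	4.7	0.4	0
MPW15.1	Gm15_2915560	2	5.1	0.4	0
MPW15.2	Gm15_BLOCK93	3	4.0	0.4	0
MPW15.3	Gm15_30923425	2	2.2	0.2	0
MPW15.4	Gm15_BLOCK409	12	8.2	1.3	0
MPW16.1	Gm16_2912151	2	2.4	0.2	0
MPW16.2	Gm16_7534785	2	2.5	0.2	0
MPW16.3	Gm16_BLOCK365	2	9.2	0.8	0
MPW17.1	Gm17_BLOCK344	7	3.1	0.4	0
MPW17.2	Gm17_BLOCK388	3	6.2	0.6	0
MPW18.1	Gm18_BLOCK736	3	3.7	0.3	0
MPW19.1	Gm19_45043655	2	3.1	0.2	0
MPW19.2	Gm19_BLOCK554	5	8.2	0.9	0
MPW19.3	Gm19_46882319	2	3.4	0.3	0
MPW20.1	Gm20_6329124	2	4.2	0.3	0
MPW20.2	Gm20_BLOCK210	4	9.1	0.9	0
MPW20.3	Gm20_BLOCK429	2	11.8	1.0	0
MPW20.4	Gm20_BLOCK468	2	2.3	0.2	0
MPW20.5	Gm20_39658098	2	6.3	0.5	1
MPW20.6	Gm20_41737971	2	2.3	0.2	0
MPW20.7	Gm20_BLOCK531	5	5.3	0.6	0
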