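qtl	marker	n_alleles	neg_log10_p	r2_percent	shared
MPH1.1	Gm01_BLOCK493	4	8.3	0.9	0
MPH1.2	Gm01_BLOCK546	3	5.6	0.6	0
MPH2.1	Gm02_161337	2	4.7	0.4	0
MPH2.2	Gm02_BLOCK299	5	12.1	1.4	0
MPH2.3	Gm02_50652770	2	7.0	0.6	0
MPH4.1	Gm04_BLOCK232	8	5.4	0.8	0
MPH4.2	Gm04_BLOCK490	7	5.1	0.8	0
MPH4.3	Gm04_43717074	2	2.2	0.2	0
MPH4.4	Gm04_47582011	2	6.6	0.6	0
MPH5.1	Gm05_10333534	2	4.1	0.3	0
MPH5.2	Gm05_18374832	2	4.2	0.4	1
MPH6.1	Gm06_BLOCK172	3	9.7	1.0	0
MPH6.2	Gm06_BLOCK208	7	8.2	1.1	0
MPH6.3	Gm06_34868214	2	3.3	0.3	0
MPH6.4	Gm06_BLOCK491	12	16.7	2.4	0
MPH6.5	Gm06_BLOCK576	3	13.2	1.4	1
MPH7.1	Gm07_BLOCK25	4	25.9	2.8	0
MPH7.2	Gm07_16348924	2	2.9	0.2	0
MPH7.3	Gm07_BLOCK194	2	9.5	0.9	0
MPH7.4	Gm07_BLOCK272	2	5.6	0.5	0
MPH7.5	Gm07_30175006	2	2.4	0.2	0
MPH7.6	Gm07_32919498	2	5.4	0.5	0
MPH7.7	Gm07_42499533	2	5.6	0.5	0
MPH8.1	Gm08_BLOCK106	6	15.5	1.9	0
MPH8.2	Gm08_BLOCK250	3	3.1	0.3	0
MPH8.3	Gm08_28738663	2	7.8	0.7	0
MPH8.4	Gm08_30916483	2	6.8	0.6	0
MPH8.5	Gm08_BLOCK466	9	9.1	1.3	1
MPH9.1	Gm09_4538598	2	2.3	0.2	0
MPH9.2	Gm09_14134401	2	3.8	0.3	0
MPH9.3	Gm09_20590481	2	2.8	0.2	0
MPH9.4	Gm09_37359880	2	3.3	0.3	0
MPH9.5	Gm09_41866356	2	2.7	0.2	0
MPH11.1	Gm11_BLOCK74	2	2.5	0.2	0
MPH11.2	Gm11_BLOCK135	5	5.0	0.6	0
MPH11.3	Gm11_27967762	2	3.3	0.3	0
MPH11.4	Gm11_BLOCK344	3	9.0	0.9	0
MPH12.1	Gm12_32591630	2	3.9	0.3	0
MPH13.1	Gm13_10222518	2	9.6	0.9	0
MPH13.2	Gm13_BLOCK177	8	19.1	2.4	0
MPH13.3	Gm13_23309035	2	6.4	0.6	0
MPH13.4	Gm13_28457573	2	2.8	0.2	0
MPH13.5	Gm13_BLOCK396	2	5.8	0.5	0
MPH14.1	Gm14_3106285	2	3.0	0.2	0
MPH14.2	Gm14_25589678	2	2.4	0.2	0
MPH14.3	Gm14_BLOCK408	6	12.3	1.5	0
MPH15.1	Gm15_BLOCK240	5	16.3	1.9	0
MPH15.2	Gm15_31242502	2	3.1	0.3	0
MPH15.3	Gm15_BLOCK383	9	22.5	2.9	0
MPH16.1	Gm16_BLOCK67	2	8.7	0.8	0
MPH16.2	Gm16_BLOCK395	3	15.4	1.6	0
MPH18.1	Gm18_4912699	2	2.5	0.2	0
MPH18.2	Gm18_7175261	2	2.4	0.2	0
MPH18.3	Gm18_BLOCK129	3	7.4	0.8	0
MPH18.4	Gm18_26517331	2	4.0	0.3	0
MPH18.5	Gm18_BLOCK434	3	4.0	0.4	0
MPH18.6	Gm18_BLOCK727	3	3.4	0.4	0
MPH18.7	Gm18_BLOCK729	3	2.2	0.2	0
MPH19.1	Gm19_37391411	2	2.4	0.2	0
MPH19.2	Gm19_41440516	2	5.3	0.5	0
MPH19.3	Gm19_42142070	2	8.5	0.8	0
MPH19.4	Gm19_42756453	2	4.8	0.4	0
MPH20.1	Gm20_BLOCK388	4	8.8	1.0	0
MPH20.2	Gm20_39658098	2	6.3	0.6	1
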