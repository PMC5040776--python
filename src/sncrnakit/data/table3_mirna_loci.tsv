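ID	Location	Strand	Distance to gene boundary	Neighbor
miR-124-5p	scaffold_29_13029–13047	+	Intron	g3043
miR-190a-3p	scaffold48_55792–55810	+	53	g13155
miR-788-5p	scaffold8_754188–754207	−	Intron	g9721
miR-383-3p	scaffold_80_111549–111567	−	Intron	g8156
miR-466g	scaffold8_19655–19673	−	94	g9475
miR1171	scaffold_70_119604–119626	+	2094	g7800
miR-467g	scaffold_26_54067–54085	−	147	g2750
miR-190a-3p	scaffold48_55792–55810	+	53	g13155
miR1427	scaffold85_42007–42025	−	110	g4652
miR2095-5p	scaffold_29_43092–43110	+	1121	g3054
miR-788	scaffold8_754188–754207	−	Intron	g9721
miR2673a	scaffold32_244540–244559	+	71	g12059
miR2673a	scaffold25_190886–190904	+	Intron	g11628
miR2673a	scaffold_15_223801–223819	−	Intron	g1786
miR2673b	scaffold32_244540–244559	+	71	g12059
miR2673b	scaffold25_190886–190904	+	Intron	g11628
miR2673b	scaffold_15_223801–223819	−	Intron	g1786
miR-2709	scaffold64_62205–62223	+	Intron	g4162
miR-2783	scaffold392_645–663	+	Intron	g5776
miR-190a-3p	scaffold48_55792–55810	+	53	g13155
miR156h-3p	scaffold151_19717–19735	−	Intron	g5461
miR4243	scaffold_15_464570–464589	−	Intron	g1895
miR-3677-5p	scaffold61_171654–171672	−	363	g4080
miR-3775	scaffold1170_174–192	−	Intron	g6228
miR3948	scaffold155_16079–16098	+	3715	g5479
miR3948	scaffold8_7775–7794	−	Intron	g9470
miR-4459	scaffold7_14624–14642	+	Intron	g9172
miR-4968-3p	scaffold_14_64946–64966	−	Intron	g1539
miR-4968-3p	scaffold34_263134–263153	−	Intron	g12318
miR-4968-3p	scaffold_24_6521–6540	−	Intron	g2572
miR-4968-3p	scaffold3_287008–287026	+	Intron	g8829
miR-5352-5p	scaffold53_49526–49544	−	Intron	g13380
miR-5455-3p	scaffold54_13491–13509	−	Intron	g3643
miR-6012-5p	scaffold14_172648–172666	−	Intron	g10243
miR6214	scaffold58_68922–68940	−	Intron	g3823
miR-6606-5p	scaffold_19_158806–158825	+	Intron	g2084
miR-7426-5p	scaffold46_187269–187287	+	Intron	g13115
miR7734-3p	scaffold21_198083–198101	+	Intron	g11335
miR-190a-3p	scaffold48_55792–55810	+	53	g13155
miR-8481-5p	scaffold1214_35–53	+	Intron	g6248
miR-8922	scaffold21_9675–9693	+	Intron	g11273
miR-8986a	scaffold_4_231055–231073	−	Intron	g184
miR-9189b	scaffold_24_289739–289757	−	Intron	g2662
miR-9400-5p	scaffold3_354824–354842	+	Intron	g8861
miR-190a-3p	scaffold48_55792–55810	+	53	g13155
miR9773	scaffold390_1391–1409	−	292	g5774
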