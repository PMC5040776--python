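ID	Location	Strand	Distance to gene boundary	Neighbor
U2.1	scaffold37_107912–108102	−	470	g12507
U2.2	scaffold43_54422–54612	−	487	g12899
U2.3	scaffold43_63239–63429	+	536	g12905
U2.4	scaffold37_118109–118299	+	329	g12510
RNase_MRP.1	scaffold1_325685–326108	+	172	g8330
U6.1	scaffold_59_650694–650810	+	315	g7427
U6.2	scaffold_80_192511–192627	+	150	g8186
U6.3	scaffold63_39552–39668	+	399	g4097
U5.1	scaffold16_469793–469909	−	959	g10739
snoZ13_snr52.1	scaffold46_213325–213430	−	394	g13123
U4.1	scaffold113_43830–43975	+	459	g5145
snoZ13_snr52.2	scaffold1_729232–729339	−	Intron	g8490
snoZ13_snr52.3	scaffold46_213071–213178	−	646	g13123
snosnR60_Z15.1	scaffold_75_65986–66075	−	Intron	g7941
Hammerhead_3.1	scaffold59_142237–142291	+	277	g3917
Hammerhead_3.2	scaffold59_152597–152651	−	257	g3922
Hammerhead_3.3	scaffold_12_734778–734832	+	262	g1296
Hammerhead_3.4	scaffold59_146486–146540	+	685	g3919
SNORD24.1	scaffold60_67979–68061	−	Intron	g3964
Afu_455.1	scaffold_11_316838–316924	−	Intron	g963
Hammerhead_3.5	scaffold25_333837–333891	+	Intron	g11689
SNORD46.1	scaffold37_225673–225759	+	1031	g12558
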