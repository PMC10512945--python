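# Published characteristics of the ten cleavage sites unmasked on membranes.
# motifs_table and motifs_text record the two printed spellings of the
# candidate motif for site 1259 (K1251 in the summary table, K1252 in the
# running text); they agree everywhere else.
position	series	motifs_table	motifs_text	position_label	masked_by
178	internal_epitope	R166;R172;R178;R196	R166;R172;R178;R196	DCB; immediately N-terminal to alpha-helix 6	C168 in alpha-helix 6; amino acids 171-176 in a loop between alpha-helix 6 and 7 of DCB
342	internal_epitope	K344	K344	linker between DCB and HUS	
469	internal_epitope	R459;R469;R477;R487	R459;R469;R477;R487	HUS; loop between alpha-helix 3 and 4	likely protected by dimerization
605	internal_epitope	K595;K604;K605;R620	K595;K604;K605;R620	linker between HUS and Sec7d	
642	internal_epitope	R627;K633;R651;K658	R627;K633;R651;K658	linker between HUS and Sec7d	
687	internal_epitope	K674;K675;R677;R682;R691;K697;K699;K700;K701	K674;K675;R677;R682;R691;K697;K699;K700;K701	linker between HUS and Sec7d	
878	internal_epitope	K859;K865;K880;R895	K859;K865;K880;R895	Sec7d; end of alpha-helix 10	Q837 in alpha-helix 8 and L851 in alpha-helix 9 of Sec7d
1259	c_tag	K1251	K1252	HDS2; middle of alpha-helix 5	I1208 in alpha-helix 3 of HDS2
1314	c_tag	R1314;R1331	R1314;R1331	linker between HDS2 and HDS3	
1369	c_tag	K1351;K1387	K1351;K1387	linker between HDS2 and HDS3	
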