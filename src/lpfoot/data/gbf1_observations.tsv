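gel_id	lane	band_id	condition	timepoint_min	detection	mass_kda	length_aa	epitope_start	epitope_end	in_control
gelB	M15	b1	membrane	15	c_tag		600			False
gelB	M15	b2	membrane	15	c_tag		545			False
gelB	M15	b3	membrane	15	c_tag		490			False
gelC	M15	b1	membrane	15	internal_epitope		1136	1267	1379	False
gelC	M15	b2	membrane	15	internal_epitope		972	1267	1379	False
gelC	M15	b3	membrane	15	internal_epitope		845	1267	1379	False
gelC	M15	b4	membrane	15	internal_epitope		709	1267	1379	False
gelC	M15	b5	membrane	15	internal_epitope		672	1267	1379	False
gelC	M15	b6	membrane	15	internal_epitope		627	1267	1379	False
gelC	M15	b7	membrane	15	internal_epitope		436	1267	1379	False
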