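species	growth_on_ammonium_ethanol	genomes_in_analysis	isocitrate_lyase	malate_synthase
A. fabarum	+	1	No	No
A. lovaniensis	+	0	?	?
A. ghanensis	-	1	No	No
A. syzygii	-	0	?	?
A. pasteurianus	-	3	No	No
A. pomorum	-	1	No	No
A. peroxydans	+	0	?	?
A. indonesiensis	-	1	No	No
A. orientalis	-	1	No	No
A. cibinongensis	w	1	No	No
A. tropicalis	-	2	No	No
A. senegalensis	+	2	No	No
A. orleanensis	-	2	No	No
A. malorum	-	2	No	No
A. cerevisiae	-	2	No	No
A. nitrogenifigens	+	1	Yes	Yes
A. oeni	-	0	?	?
A. aceti	+	2	Yes	Yes
A. estunensis	+	0	?	?
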