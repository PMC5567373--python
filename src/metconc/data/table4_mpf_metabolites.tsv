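metabolite_id	name	neg_log_c_eco	neg_log_c_sce	clogp
glutamate	Glutamate	1.02	1.09	-2.69
atp	ATP	2.02	2.47	-4.55
aspartate	Aspartate	2.37	1.80	-2.41
glutamine	Glutamine	2.42	1.09	-3.38
citrate	Citrate	2.71	2.83	-2.00
malate	Malate	2.77	2.77	-1.52
acetyl_coa	Acetyl-CoA	3.22	NA	-3.54
succinate	Succinate	3.24	3.47	-0.53
succinyl_coa	Succinyl-CoA	3.63	NA	-3.94
fumarate	Fumarate	3.94	2.78	-0.17
sam	S-adenosyl-L-methionine	3.74	NA	-5.08
alanine	Alanine	2.59	1.61	-3.12
gtp	GTP	2.31	3.23	-5.53
g6p	D-Glucose 6-phosphate	NA	2.43	-3.28
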