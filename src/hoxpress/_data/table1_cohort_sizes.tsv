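organ	category	n_healthy	n_tumor
Adrenal_Gland	PCPG	128	185
Brain	LGG	105	527
Brain	GBM	105	173
Breast	BRCA	179	1253
Colon	COAD	308	455
Esophagus	ESCA	273	195
Leukemia	LAML	337	173
Liver	LIHC	110	422
Lung	LUAD	288	598
Lung	LUSC	288	551
Pancreas	PAAD	167	183
Prostate	PRAD	100	556
Stomach	STAD	175	451
Thyroid	THCA	280	571
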