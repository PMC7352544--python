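gene	cancer_type	fold_change	km_significant
HOXA5	GBM	7.0	0
HOXA7	LAML	3.6	1
HOXA9	GBM	3.7	0
HOXA10	GBM	6.2	0
HOXA10	PAAD	3.4	0
HOXA10	STAD	4.3	0
HOXB4	GBM	4.3	0
HOXB8	PAAD	3.0	0
HOXB9	LUSC	4.6	0
HOXB9	STAD	6.2	0
HOXB13	ESCA	6.8	0
HOXC4	GBM	5.5	0
HOXC4	LGG	3.5	1
HOXC6	GBM	5.9	0
HOXC8	LUSC	3.2	0
HOXC8	PAAD	3.5	0
HOXC8	STAD	4.6	0
HOXC9	PAAD	3.4	0
HOXC10	ESCA	4.7	0
HOXC10	LUSC	5.1	0
HOXC10	STAD	7.5	0
HOXC11	BRCA	3.7	0
HOXC13	BRCA	4.3	0
HOXC13	ESCA	5.1	0
HOXD3	GBM	4.3	0
HOXD9	LIHC	3.0	0
HOXD10	LUSC	3.6	0
HOXD11	ESCA	5.2	0
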