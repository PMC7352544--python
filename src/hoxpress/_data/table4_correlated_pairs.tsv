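cancer_type	gene_a	gene_b
ESCA	HOXA10	HOXB5
ESCA	HOXA10	HOXB6
ESCA	HOXA10	HOXB7
ESCA	HOXB5	HOXB6
ESCA	HOXB5	HOXB7
ESCA	HOXB6	HOXB7
ESCA	HOXC10	HOXC8
GBM	HOXA3	HOXC10
GBM	HOXA10	HOXC10
GBM	HOXB2	HOXB3
GBM	HOXB4	HOXB5
GBM	HOXB5	HOXB6
LAML	HOXA3	HOXA5
LAML	HOXA10	HOXA9
LIHC	HOXD3	HOXD9
LIHC	HOXD8	HOXD9
LUSC	HOXC8	HOXC9
STAD	HOXC6	HOXC8
STAD	HOXC6	HOXC9
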