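cancer_type	gene
LGG	HOXA1
LGG	HOXA4
LGG	HOXA7
LGG	HOXA11
LGG	HOXB13
LGG	HOXC4
LGG	HOXD3
LGG	HOXD4
LGG	HOXD8
LGG	HOXD9
LGG	HOXD10
GBM	HOXB2
GBM	HOXB9
LAML	HOXA7
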