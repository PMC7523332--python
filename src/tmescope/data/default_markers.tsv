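set_name	gene
ETC	EPCAM
ETC	KRT19
CAF	COL1A1
CAF	ACTA2
CAF	SPARC
EMT	CDH2
EMT	SNAI2
EMT	ZEB1
TIL	CD3D
TIL	IL7R
TIL	CD3G
TAM	CD68
Endo	KDR
Endo	VWF
DC	FCER1A
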