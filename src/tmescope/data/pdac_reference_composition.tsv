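patient_id	tissue	CAF	DC	EMT	Endo	ETC	TAM	TIL
P01	primary	8.6	3.7	73.1	3.2	9.3	0.5	1.2
P02	primary	2.8	6.3	0.7	0.0	51.7	8.4	30.1
P03	primary	10.7	0.1	82.0	3.7	1.7	1.6	0.1
P04	primary	24.6	< 0.1	2.8	< 0.1	72.7	< 0.1	< 0.1
P05	primary	68.3	1.8	< 0.1	2.3	17.7	8.1	1.8
P06	primary	33.4	3.8	< 0.1	3.1	55.1	4.2	0.4
P07	primary	14.1	4.5	< 0.1	1.0	17.6	53.7	9.1
P08	primary	14.3	3.4	< 0.1	1.2	74.0	6.7	0.4
P09	primary	27.2	1.8	< 0.1	2.8	37.0	31.1	0.2
P10	primary	8.7	2.0	< 0.1	< 0.1	85.1	4.1	0.1
MET01	metastasis	< 0.1	< 0.1	< 0.1	< 0.1	97.6	2.1	0.2
MET02	metastasis	< 0.1	< 0.1	< 0.1	< 0.1	97.0	2.7	0.3
MET03	metastasis	< 0.1	< 0.1	< 0.1	< 0.1	30.4	30.4	39.2
MET04	metastasis	< 0.1	< 0.1	< 0.1	< 0.1	45.8	36.5	17.7
MET05	metastasis	< 0.1	< 0.1	< 0.1	< 0.1	95.6	3.2	1.2
MET06	metastasis	< 0.1	< 0.1	< 0.1	< 0.1	93.4	3.8	2.8
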