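set_name	gene
exhaustion	TIGIT
exhaustion	CTLA4
exhaustion	PDCD1
exhaustion	HAVCR2
exhaustion	LAG3
exhaustion	LAYN
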