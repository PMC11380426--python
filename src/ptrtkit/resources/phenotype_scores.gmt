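naive	editable default naive T-cell set (non-authoritative)	CCR7	TCF7	LEF1	SELL	IL7R
cytotoxicity	editable default cytotoxicity set (non-authoritative)	GZMB	PRF1	GNLY	NKG7	IFNG	KLRG1
exhaustion	editable default exhaustion set (non-authoritative)	PDCD1	TOX	LAG3	HAVCR2	CTLA4	TIGIT
senescence	editable default senescence set (non-authoritative)	B3GAT1	KLRG1	CDKN1A	CDKN2A
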