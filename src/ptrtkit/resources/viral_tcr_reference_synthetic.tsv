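cdr3_aa_beta	v_gene	species
CASSVIRALAEQFF	TRBV9	synthetic-virus-A
CASSEPSTEINYF	TRBV5	synthetic-virus-B
CASSFLVENAEQF		synthetic-virus-C
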