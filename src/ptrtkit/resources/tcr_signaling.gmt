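REACTOME_TCR_SIGNALING	MSigDB-style TCR signaling set (editable; ships as a default, not an authoritative copy)	CD3D	CD3E	CD3G	CD247	LCK	FYN	ZAP70	LAT
REACTOME_DOWNSTREAM_TCR_SIGNALING	downstream TCR signaling	PLCG1	PRKCQ	CARD11	BCL10	MALT1	NFKB1	REL	MAP3K7
REACTOME_PHOSPHORYLATION_OF_CD3_AND_TCR_ZETA_CHAINS	CD3 / TCR zeta phosphorylation	CD3D	CD3E	CD3G	CD247	LCK	PTPRC	CSK	PAG1
REACTOME_GENERATION_OF_SECOND_MESSENGER_MOLECULES	second messenger generation	PLCG1	ITPR1	PRKCA	RASGRP1	SOS1	GRAP2	LAT	LCP2
BIOCARTA_TCRA_PATHWAY	TCR alpha pathway	CD3D	CD28	LCK	FYN	GRB2	SOS1	RAF1	MAP2K1
REACTOME_TRANSLOCATION_OF_ZAP_70_TO_IMMUNOLOGICAL_SYNAPSE	ZAP70 translocation	ZAP70	CD3D	CD3E	CD3G	CD247	LCK	PTPN6	UBASH3A
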