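study	cohort	n_cells
human_integration	aml_patients	25868
human_integration	healthy_donors	31318
mouse_model	control_group	21410
mouse_model	runx1_runx1t1_group	22040
aml_mds_integration	aml_mds_patients	18237
aml_mds_integration	healthy_donors	5417
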