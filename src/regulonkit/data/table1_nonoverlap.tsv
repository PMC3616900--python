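lineage	tfs	target_genes	target_operons	interactions
Streptococcaceae	69	779	397	470
Lactobacillaceae	79	539	289	328
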