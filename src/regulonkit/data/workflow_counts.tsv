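workflow	n_regulons
1	41
2	14
3	47
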