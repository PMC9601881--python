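group	n_sequences	note
syk_jawed_vertebrates	89	Syk orthologs from jawed vertebrates
zap70_jawed_vertebrates	87	ZAP-70 orthologs from jawed vertebrates
invertebrate_or_jawless	7	single Syk-family kinases from invertebrates and jawless vertebrates
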