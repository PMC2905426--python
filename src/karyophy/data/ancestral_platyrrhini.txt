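# Human homologous syntenic associations of the inferred ancestral
# New World primate (Platyrrhini) karyotype, one form label per line.
3a/21
5/7a
2b/16b
8a/18
14/15a
10a/16a
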