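f2003f747625b3d5f3906ea74f81ae6210beaad085051ccf7d3fd35c2214aff9  hsa_pir.tsv
2e814a9949dae2ee1399c57483d395c00f5070665a859a7d8a279545fe16b2df  hsa_ccr.tsv
359d45da422069bf194003e21e6abc122b629f914da7a8e42e837d7ef3792705  soe_ccr.tsv
c646db0b694049b15df8365d86db0962bf92575b02726c815163b6a335b08e0d  hsa_cut_synthetic.tsv
9d381ad18999adbe692f23d56df03a7bdae1ab42c0ae79a080835c2ab4c56e6b  ancestral_platyrrhini.txt
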