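# Keyword-named gene sets: the NFKB token appears in 80% of enriched set
# names vs 10% of background names.
genesets:
  n_sets: 300
  n_enriched: 30
  keyword_vocab: [APOPTOSIS, HYPOXIA, ANDROGEN, ESTROGEN, MYC, P53, WNT,
                  CYCLE, DNA, REPAIR, IMMUNE, INFLAMMATION, METABOLISM,
                  SIGNALING, RESPONSE, TARGETS, EPITHELIAL, MESENCHYMAL,
                  STEM, DIFFERENTIATION, PROLIFERATION, ADHESION, MIGRATION,
                  KINASE, RECEPTOR, UP, DN]
  planted_keyword: NFKB
  enrichment_rate: 0.8
  background_rate: 0.1
  seed: 11
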