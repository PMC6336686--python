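# Peak set + TSS + DE table: 50 planted bound genes each receive a peak
# within 7.5 kb of their TSS and an elevated |log2FC| in the DE table.
cistrome:
  n_chroms: 4
  chrom_length: 50000000
  n_peaks: 600
  n_genes: 2000
  planted_bound_gene_ids: [
    G00000, G00001, G00002, G00003, G00004, G00005, G00006, G00007, G00008, G00009,
    G00010, G00011, G00012, G00013, G00014, G00015, G00016, G00017, G00018, G00019,
    G00020, G00021, G00022, G00023, G00024, G00025, G00026, G00027, G00028, G00029,
    G00030, G00031, G00032, G00033, G00034, G00035, G00036, G00037, G00038, G00039,
    G00040, G00041, G00042, G00043, G00044, G00045, G00046, G00047, G00048, G00049]
  bound_effect: 0.5
  window: 7500
  seed: 11
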