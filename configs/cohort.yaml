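# Synthetic tumor/normal cohort with a planted miRNA-target axis (both edge
# signs), outlier genes and a survival subgroup. Gene ids are G00000..;
# miRNA ids are miR-0000..
cohort:
  n_tumors: 200
  n_normals: 40
  n_genes: 400
  n_mirnas: 4
  noise_sd: 1.0
  seed: 11
  planted_axis:
    - mirna_id: miR-0000
      target_gene_ids: [G00000, G00001, G00002, G00003, G00004,
                        G00005, G00006, G00007, G00008, G00009]
      r_low: 0.7
      r_high: 0.1
    - mirna_id: miR-0000
      target_gene_ids: [G00010, G00011, G00012, G00013, G00014]
      r_low: -0.1
      r_high: -0.7
  planted_outliers:
    gene_ids: [G00020, G00021, G00022]
    z_effect: 5.0
    tumor_fraction: 0.45
  planted_survival:
    subgroup_gene_ids: [G00030, G00031]
    hazard_ratio: 2.0
    event_fraction: 0.4
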