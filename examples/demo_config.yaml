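seed: 0
chromosome_lengths:
  chr1: 5000000
  chr2: 5000000
  chr3: 5000000
  chr4: 5000000
track_specs:
  RLFS: {n_elements: 100, length_mean: 1000.0}
  GQ: {n_elements: 100, length_mean: 1000.0}
  CpGi: {n_elements: 100, length_mean: 1000.0}
  CRM: {n_elements: 100, length_mean: 1000.0}
  SCS-S: {n_elements: 100, length_mean: 1000.0}
  DHS_prom: {n_elements: 100, length_mean: 1000.0}
  DHS_enh: {n_elements: 100, length_mean: 1000.0}
  DHS_dyadic: {n_elements: 100, length_mean: 1000.0}
  DHS_rest: {n_elements: 100, length_mean: 1000.0}
  DR: {n_elements: 100, length_mean: 1000.0}
  STR: {n_elements: 100, length_mean: 1000.0}
  MR: {n_elements: 100, length_mean: 1000.0}
  IR: {n_elements: 100, length_mean: 1000.0}
  Z: {n_elements: 100, length_mean: 1000.0}
  SR: {n_elements: 100, length_mean: 1000.0}
  MS: {n_elements: 100, length_mean: 1000.0}
  LC: {n_elements: 100, length_mean: 1000.0}
  APR: {n_elements: 100, length_mean: 1000.0}
  LTR: {n_elements: 100, length_mean: 1000.0}
  RT: {n_elements: 100, length_mean: 1000.0}
  SCS-G: {n_elements: 100, length_mean: 1000.0}
enrichment:
  GQ: 8.0
  RLFS: 6.0
  CpGi: 5.0
  DHS_prom: 5.0
  CRM: 4.0
  MR: 3.0
  SR: 3.0
n_samples: 112
gene_spec: {n_genes: 100, length_mean: 30000.0}
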