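# Column-name mapping from each predictor's export dialect onto the
# canonical PredictionRecord fields.  Edit here (or pass a custom mapping
# file) when a tool changes its export headers; no code change needed.
diana:
  mirna: "mirna_name"
  gene: "ensembl_gene_id"
  mitg_score: "mitg_score"
mirdb:
  mirna: "miRNA Name"
  gene: "Gene Symbol"
  prediction_score: "Target Score"
targetscan:
  mirna: "miRNA"
  gene: "Gene Symbol"
  context_plus: "Context++ score"
  pct: "PCT"
  site_start: "UTR start"
  site_end: "UTR end"
rna22:
  mirna: "miRNA"
  gene: "gene"
  p_value: "p_value"
  site_start: "site_start"
  site_end: "site_end"
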