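{
 "required_stages": [
  "inputs",
  "qc",
  "differential_expression",
  "signature_stats",
  "resampling",
  "coexpression",
  "projection",
  "recovery"
 ],
 "stage_required_keys": {
  "inputs": ["n_genes", "n_samples", "simulated", "wall_time_s"],
  "qc": ["n_excluded", "excluded", "n_samples_kept", "wall_time_s"],
  "differential_expression": ["ctl_acute", "ctl_chronic", "asd_acute", "asd_chronic", "baseline"],
  "signature_stats": ["ctl", "asd"],
  "resampling": ["ctl_acute", "ctl_chronic", "asd_acute", "asd_chronic"],
  "coexpression": ["n_input_genes", "wall_time_s"],
  "projection": ["n_signature_genes", "wall_time_s"],
  "recovery": ["n_baseline_de", "combined_counts", "wall_time_s"]
 }
}
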