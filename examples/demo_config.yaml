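# End-to-end demo: simulate both reference experiments, then run all
# three analysis stages.
#
#   clipenrich run-all --config examples/demo_config.yaml
#
out: demo_out
seed: 7
simulate:
  rrna:
    reference_name: 18S
    read_length: 10
    library_sizes: {ip_untreated: 50000, ip_treated: 50000, trunc: 2000}
    footprints:
      - {start: 1117, end: 1195, fold: 3, condition_set: [untreated, treated]}  # ES7
      - {start: 710, end: 766, fold: 3, condition_set: [treated]}               # ES6b/c
    samples:
      - {name: ip_untreated, role: ip, condition: untreated}
      - {name: ip_treated, role: ip, condition: treated}
      - {name: trunc, role: truncation_control, condition: untreated}
  transcriptome:
    read_length: 10
    library_sizes: {ip: 20000, ko: 20000}
    samples:
      - {name: ip, role: ip, condition: treated}
      - {name: ko, role: knockout, condition: treated}
    genes:
      n_genes: 4
      n_decoys: 2
      cds_footprint: {start: 101, end: 140, fold: 4, condition_set: [treated]}
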