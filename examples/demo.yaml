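# Demo configuration: a reduced synthetic study exercising every stage.
# Run with:  replilicense run -c examples/demo.yaml --outdir demo_run
seed: 7
simulate:
  layout:
    - [chr1, 5000000]
    - [chr2, 5000000]
  n_nfib_sites: 120
  n_orc1_independent: 50
  n_atac_close_sites: 30
  n_atac_unchanged_sites: 150
  n_s2_origins: 50
  n_s3_origins: 40
  n_dormant_origins: 20
  n_ns_decoys: 40
  n_weakened_A_bins: 8
  n_planted_cnas: 8
  n_fragile_sites: 5
  n_spontaneous_losses: 2
  n_decoy_loci: 10
  n_cohorts: 3
  n_patients: 120
em_n_traces: 100
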