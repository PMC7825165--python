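# Minimal end-to-end run: simulate an 8-individual two-group cohort,
# call and merge CNVs, compare against the bundled toy interval sets,
# and scan for differentiated regions.  `cnvpop run --config pipeline.yaml`
# (run from this directory).
seed: 7
output_dir: demo_out
window_size: 100
simulate:
  chromosomes:
    - [chr1, 1000000]
    - [chr2, 500000]
  individuals:
    - [s0, horned]
    - [s1, horned]
    - [s2, horned]
    - [s3, horned]
    - [s4, polled]
    - [s5, polled]
    - [s6, polled]
    - [s7, polled]
  n_shared_cnvs: 8
  n_group_specific_cnvs: 1
  diff_freq_high: 1.0
  diff_freq_low: 0.0
compare:
  references:
    - name: toy_catalogue
      path: toy_reference_cnvrs.bed
      dialect: bed
  qtl:
    path: toy_qtl.tsv
    dialect: one-based
  genes:
    path: toy_genes.bed
    dialect: bed
    min_fraction: 0.5
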