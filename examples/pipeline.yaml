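# Full-pipeline configuration with the published-parameter profile.
# Generate the inputs first:  germscan simulate -o scenario --seed 42
germline_reads: [scenario/germline_reads.fq]
somatic_reads: [scenario/somatic_reads.fq]
scaffolds: scenario/germline.fa
out_dir: germscan_out
seed: 42

k: 31
node_k: 29
abundance_multiplier: 3
enrichment:
  min_interval_span: 5000     # v
  report_min_length: 0        # l
  min_depth_1: 10             # a
  min_depth_2: 10             # b
  max_depth_1: 12000000       # A
  max_depth_2: 12000000       # B
filter:
  min_score: 5.0
  min_span: 40000
merge:
  replace_identity: 0.90
  replace_coverage: 0.80
  known_identity: 0.99
  seed_word_size: 11
cluster:
  identity_threshold: 0.80
  min_coverage_shorter: 0.30  # aS
  min_coverage_longer: 0.30   # aL
  merge_min_hits: 4
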