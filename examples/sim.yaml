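seed: 1
outdir: sim_out
simulate:
  genome_length: 120000
  n_strains: 2
  snp_rate: 0.005
  indel_rate: 0.0002
  indel_size_max: 10
  n_genes: 40
  marks: [H3K4me3, H3K9ac, H3K14ac, H4K12ac, H3K4me1]
  n_reads_per_sample: 200000
  n_replicates: 3
  fuzzy_fraction: 0.05
  n_shifted: 20
  shift_range: [20, 60]
  n_evicted: 5
  dispersion: 0.05
  planted_sneps:
    - [nuc00050, H3K14ac, 2.0]
    - [nuc00120, H3K4me3, -1.8]
thresholds:
  chunk: 90
  min_cur_length: 4000
  max_indel: 30
  fdr: 0.0001
  p: 0.01
  delta_cutoff: 10
  window: 10
  permutations: 3
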