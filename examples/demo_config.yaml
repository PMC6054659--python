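# Demo pipeline configuration: simulation-backed end-to-end run.
# Two populations ("A" = reference breed, "B" = diverged breed carrying a
# 1 Mb selective sweep), modest sizes so the whole run takes a few seconds.
seed: 11
simulate:
  n_individuals: 20
  n_markers: 800
  chrom_length_bp: 48000000
  target_fst: 0.05
  sweep:
    pop: B
    focal_marker_index: 400
    core_length_bp: 1000000
    carrier_freq: 0.9
fst:
  n_perm: 200
scan:
  total_tail: 0.01
structure:
  n_boot: 50
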