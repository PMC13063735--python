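# Demo pipeline configuration: a small synthetic genome with three TE
# families, one of which (MERS1A, an ERV1-like LTR family) propagated a
# Sox2-like motif by retrotransposition.
seed: 11
tf: Sox2
pwm: SOX2_SYNTH
simulate:
  genome_length: 600000
  chrom: chrS
  families:
    - subfamily: MERS1A
      family: ERVS
      class_family: LTR/ERVS
      n_copies: 50
      consensus_length: 400
      divergence: 0.10
      clade: Simiiformes
      motif:
        pwm: SOX2_SYNTH
        position: 250
        fraction: 0.5
        cells: [NPC]
    - subfamily: AmnSINE-X
      family: AmnSINE
      class_family: SINE/AmnSINE
      n_copies: 50
      consensus_length: 300
      divergence: 0.25
      clade: Amniota
      motif:
        pwm: SOX2_SYNTH
        position: 120
        fraction: 0.4
        cells: [ESC, NPC]
        shared_fraction: 0.5
    - subfamily: L3X
      family: CR1
      class_family: LINE/CR1
      n_copies: 40
      consensus_length: 350
      divergence: 0.20
      clade: Eutheria
  n_background_summits:
    ESC: 60
    NPC: 60
  n_input_reads: 30000
  segment_size: 200
  enhancer_prob_bound:
    ESC: 0.9
    NPC: 0.9
  transition_quiescent_prob: 0.6
  n_genes: 80
  effect_fold: 8.0
  effect_prob: 0.7
  expression_noise_sd: 0.3
  ortholog_loss: 0.0
params:
  sample_size: 20000
  window_size: 50
  min_match: 0.95
  pseudocount: 0.01
  alpha: 0.001
  strong_log2fc: 3.0
  motif_p: 0.01
  min_consensus_hits: 5
  conservation_window: 2000
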