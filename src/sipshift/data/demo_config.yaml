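# Three-soil paired-gradient SIP demo (synthetic).
#
# Two pre-exposed soils (D, F) share one labelled guild of five taxa; the
# control soil (W) has a disjoint guild — the signature of a community
# adapted to the substrate. An early timepoint with weak labelling (day 18,
# 10 atom% 13C in the guild's DNA) and a late one with strong labelling
# (day 32, 99 atom%) let the whole-community qPCR shift check pick the
# timepoint worth screening, after which per-taxon detection recovers the
# guilds.
seed: 20251001
simulate:
  soils: [D, F, W]
  replicates: 3
  n_taxa: 50
  labelled:
    D: [T001, T002, T003, T004, T005]
    F: [T001, T002, T003, T004, T005]
    W: [T006, T007, T008, T009, T010]
  labelled_abundance: [0.02, 0.04]
  gc_range: [0.30, 0.70]
  abundance_sigma: 1.2
  timepoints:
    - {days: 18, labelled_atom13c: 0.10}
    - {days: 32, labelled_atom13c: 0.99}
  gradient:
    n_fractions: 12
    density_min: 1.665
    density_max: 1.775
    band_sigma: 0.006
    smear: 0.03
    seq_depth: 3240
    qpcr_cv: 0.10
    overdispersion: 200.0
detect:
  com_threshold: 0.010
  heavy_k: 2
  min_abund: 0.001
  permutations: 0
  alpha: 0.05
total_shift_tolerance: 0.003
log_level: INFO
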