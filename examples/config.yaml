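# A small end-to-end run: 20 founders, five generations with a 40%
# chance of full-sib matings, two chromosomes of 2,000 markers each.
seed: 11
pedigree:
  n_founders: 20
  n_generations: 5
  progeny_per_mating: 2
  mating_policy: close_kin
  close_kin_prob: 0.4
genome:
  n_chromosomes: 2
  markers_per_chromosome: 2000
  genotyping_error: 0.001
gene_drop:
  n_replicates: 100000
roh:
  method: hmm
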