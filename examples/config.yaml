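# Annotated isosip pipeline configuration.
# Every stochastic step derives its randomness from `seed`; the same
# config + seed reproduces every output byte-for-byte.
seed: 1

# Shotgun metagenome samples to simulate and quantify. Each sample is a
# synthetic community screened with the isoA/recA translated search; with
# two or more samples a pairwise fold-ratio table is also written.
samples:
  soil:
    n_taxa: 100              # genomes in the community
    carrier_fraction: 0.01   # fraction of genomes carrying one isoA copy
    abundance: uniform       # uniform | dirichlet (symmetric, alpha 1)
    n_reads: 20000           # shotgun reads to simulate
    read_length: 150         # bp
    sub_error_rate: 0.005    # per-base substitution probability
  leaf:
    n_taxa: 500
    carrier_fraction: 0.002
    abundance: uniform
    n_reads: 20000
    read_length: 150

# Translated-search statistics (defaults shown; gapped BLOSUM62 11/1).
search:
  evalue_cutoff_target: 1.0e-4   # isoA screen
  evalue_cutoff_norm: 1.0e-6     # recA screen
  min_verify_identity: 50        # percent; strict "< 50" discards

# A paired 13C/12C gradient experiment with labelled-taxon calling.
sip:
  n_taxa: 12
  abundance: uniform
  labeled_taxa: [taxon_0003, taxon_0008]  # fully 13C-labelled taxa
  min_fold_13C: 5          # heavy/light fold-change to call labeled
  min_control_ratio: 2     # fc_13C / fc_12C must reach this ratio
  pseudocount: 1.0e-4      # RA floor before ratios

# Synthetic contig screen: plants a complete cluster (isoABCDEFGHIJ +
# aldH1), a core-only cluster (isoABCDEF) and an unrelated contig, then
# assigns homologs and classifies the clusters.
screen:
  demo: true
  max_gap: 5000            # bp between consecutive cluster genes
  divergence: 0.10         # how far planted proteins drift from references
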