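# Example configuration for `slimfoot run --config examples/config.yaml`.
# Exactly one of `simulation:` / `inputs:` may be present.
seed: 1
outdir: slimfoot_out

simulation:
  n_sites_per_class: 25      # sites per promoter class (C1..C4b)
  fragments_per_site: 400    # ChIP fragments per site
  mnase_level: 1.0           # relative digestion level (1/9/27 scale)
  boundary_noise_sd: 10.0    # bp of end overhang noise at unit MNase

netseq_reads_per_site: 400
nuc_fragments_per_site: 500
shift_bp: 25                 # configured depletion-induced dyad movement

analysis:
  k_clusters: 4
  bottom_fraction: 0.15

# File-driven alternative (replaces the simulation block):
# inputs:
#   fragments: chip_fragments.bed
#   peaks: peaks.narrowPeak
#   motifs: motifs.bed
#   tss: tss.tsv
#   telomeres: telomeres.bed
#   netseq: netseq.bed
#   nuc_before: nuc_before.bed
#   nuc_after: nuc_after.bed
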