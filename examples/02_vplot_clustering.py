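"""Classify binding sites into promoter configurations by fragment length.

Simulates the default five-class site panel, summarizes each site as a
21-bin fragment-length histogram (40-250 bp, 10 bp bins), clusters the
histograms with K-means (K=4), and scores the TSS-distal asymmetry of
long (160-220 bp) co-bound fragments per cluster.
"""

import numpy as np

import slimfoot as sf

params = sf.SimulationParams(seed=11)       # 50 sites/class, 500 fragments/site
panel = sf.build_site_panel(params)
chip = sf.simulate_chip_fragments(panel, params, seed=12)
anchors = panel.anchors()

profiles = [p for p in sf.profiles_for_sites(
    chip, anchors.drop(columns=["class_label"])) if not p.empty]
result = sf.cluster_profiles(profiles, K=4, seed=11)

print(f"sites clustered: {len(profiles)}")
print("cluster  size  long-fraction  mean asymmetry")
ids = [p.peak_id for p in profiles]
for k in sorted(result.sizes()):
    members = [i for i, lab in zip(ids, result.labels) if lab == k]
    sel = anchors[anchors["name"].isin(members)].drop(
        columns=["class_label"]).reset_index(drop=True)
    asym = sf.long_fragment_asymmetry(chip, sel).dropna()
    print(f"{k:>7}  {result.sizes()[k]:>4}  {result.long_fractions[k-1]:>13.3f}"
          f"  {asym.mean():>14.3f}")

print()
print("Clusters are ordered by the mass of long (>=160 bp) fragments:")
print("cluster 1 is dominated by short factor-only footprints, cluster 4")
print("by factor+nucleosome co-bound fragments.  A positive asymmetry")
print("means those long fragments lie TSS-distal, i.e. the factor")
print("preferentially protects the -1 nucleosome.")
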