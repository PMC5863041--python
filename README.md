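# slimfoot

Fragment-length footprinting of transcription-factor–nucleosome
architecture from paired-end MNase ChIP data.

MNase digests DNA that is not shielded by bound protein, so the
fragments recovered from an MNase-based ChIP experiment carry structure:
~30 bp fragments whose ends abut the factor's binding motif report the
factor's own footprint, ~147 bp fragments report nucleosomes, and a
distinct 160–220 bp class reports single molecules protected by the
factor *plus* an adjacent nucleosome.  `slimfoot` turns that structure
into biology for a panel of binding sites:

* **footprint boundaries** from stacked 5′/3′ fragment ends around
  oriented motifs (width = modal 3′ boundary − modal 5′ boundary + 1);
* **V-plots** — 2-D histograms of fragment midpoint offset × length —
  and per-site 21-bin fragment-length histograms (40–250 bp, 10 bp);
* **K-means classification** (K = 4) of sites into promoter
  configuration clusters, canonically ordered by long-fragment mass,
  after motif-presence and bottom-15% read-depth filters;
* **TSS-distal asymmetry** of the long co-bound fragments (score
  `(upstream − downstream)/total`; expectation `2p − 1` under distal
  placement probability p), diagnosing preferential −1-nucleosome
  contact;
* **NET-seq directionality**: strand-split coverage of Pol II 3′ ends
  (extended 20 bp 5′-ward), an aborted-upstream-transcript score, and a
  deterministic 1-D two-means split of the long-fragment cluster into
  "locked" (4a) and "pushed" (4b) subclasses;
* **nucleosome-shift quantification** from occupancy profiles (fragment
  centers ± 25 bp) before vs after chromatin-remodeler depletion, with
  negative shifts meaning movement toward the binding site;
* peak bookkeeping: cross-method matching (< 64 bp center distance),
  normalized coverage (summit ± 75 bp, per 10⁶ fragments), ORF-location
  classification, nearest-TSS anchors (> 256 bp discarded), IUPAC
  consensus scanning, random background sampling.

Because the analyses are defined by recovery of known structure, the
package ships a first-class **synthetic chromatin simulator** with
ground-truth labels: five promoter classes (C1 isolated factor, C2
continuum, C3 symmetric bimodal, C4a locked, C4b pushed), MNase-level
dependence, NET-seq sense/antisense patterns including aborted
transcripts, and depletion-induced nucleosome repositioning.  See
`docs/methods.md` for models, parameters and limitations.

## Worked example

```sh
python examples/02_vplot_clustering.py
```

```
sites clustered: 250
cluster  size  long-fraction  mean asymmetry
      1    50          0.096           0.080
      2    50          0.155           0.122
      3    50          0.490           0.017
      4   100          0.721           0.792
```

250 simulated sites (50 per class; C4a and C4b share a ChIP signature)
are clustered by their fragment-length histograms alone.  The four
clusters recover the simulated classes exactly: cluster 1 is dominated
by short factor-only fragments (long-fraction 0.10), cluster 4 by
co-bound fragments (0.72), and only cluster 4 shows strong TSS-distal
asymmetry (0.79 ≈ 2 × 0.9 − 1, the simulator's distal-side
probability) — the signature of a factor bound together with its −1
nucleosome.  `examples/01_footprint.py` recovers the 30 bp footprint
(modal boundaries −15/+14), and `examples/03_netseq_shift.py` splits
cluster 4 by aborted transcripts (agreement 1.00) and recovers the
configured ±25 bp dyad shifts, including the locked C4a −1 nucleosome
(shift 0).

A YAML-config-driven end-to-end run (simulation → filters → footprint →
V-plot → clustering → asymmetry → NET-seq split → shifts, with TSV/BED
artifacts and a JSON summary) is available as a library call
(`slimfoot.run_analysis`) or from the shell:

```sh
slimfoot fixture --out demo --seed 5      # miniature dataset, all formats
slimfoot run --config cfg.yaml --seed 1 --out results/
```

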