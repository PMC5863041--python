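# Methods

`slimfoot` analyses paired-end MNase ChIP fragments around
transcription-factor binding sites.  Because MNase digests DNA that is
not shielded by bound protein (up to protection edges or cross-linking
points), each fragment's length and end positions report on the local
protein architecture: ~30 bp fragments mark the factor's own footprint,
~147 bp fragments mark nucleosomes, and 160–220 bp fragments mark a
single DNA molecule protected by the factor *and* an adjacent nucleosome
("co-bound").  The package quantifies these signals and classifies
promoters by them.  All coordinates are 0-based half-open; "oriented"
offsets are measured from an anchor (motif center or TSS) with the
nearest-TSS or motif direction as positive.

## Analysis operators

**Footprint estimation** (`footprint`).  Fragment 5′/3′ ends are stacked
in oriented coordinates around anchors; for a minus-oriented anchor the
roles of start/end swap so "5′" is always motif-upstream.  The 3′ end of
`[start, end)` is `end − 1`, making both ends inclusive base positions,
so the footprint width `R − L + 1` of a region protected over
`[−15, +14]` reads out as exactly 30 bp.  Boundaries are the argmax of
the 5′ profile over `[−flank, 0)` and of the 3′ profile over
`[0, +flank]` (flank default 40 bp); argmax ties break toward the
anchor.  Ends falling outside the stacking window are clipped, so the
count-conservation identity applies to in-window ends.

**V-plots and length profiles** (`vplot`).  A V-plot accumulates
(oriented midpoint offset, fragment length) counts; the midpoint is
`floor((start + end − 1)/2)` — one fixed rule for even-length fragments.
Each site's `LengthProfile` is the fraction of fragments (midpoint
within summit ± 100 bp, the default peak-region halfwidth) per 10-bp
length bin over 40–250 bp.  The 21 bins are left-closed with a
right-closed top bin — the only reading that makes 40–250 bp at 10 bp
resolution an exact partition.

**K-means classification.**  Sites are clustered on the raw 21-dim
fraction vectors (unscaled; no per-bin standardization) with
scikit-learn's k-means++ KMeans, best of 25 seeded restarts.  Clusters
are relabeled canonically by ascending centroid *long-fraction* (mass in
bins ≥ 160 bp), so cluster 1 is shortest-dominated and cluster K
co-bound-dominated.  This key orders the short-vs-long extremes
robustly; the middle clusters (continuum vs symmetric-bimodal) are
ordered by their long mass, which is one defensible convention among
several.

**Long-fragment asymmetry.**  Among fragments of length 160–220 bp
overlapping the anchor position, the score is
`(upstream − downstream)/total` midpoints in TSS-oriented coordinates
(upstream = TSS-distal).  Under binomial placement with distal
probability p the expected score is `2p − 1`.

**Pre-clustering filters** (`peaks`).  Motif-less peaks are removed
first, then the bottom `ceil(fraction × m)` of the remaining m peaks by
read count (ceiling is the unique rounding consistent with removing 140
of 929 at 15%); read-count ties break by input order.  Other peak-level
rules: peaks match across sets when center distance is *strictly* less
than 64 bp (three-way matching by connected components of pairwise
matches — the multiway convention the pairwise rule needs); per-peak
coverage is summed over summit ± 75 bp and scaled by 10⁶/library size;
peaks more than 256 bp from the nearest TSS are discarded (256 itself is
kept); nearest-TSS ties go to the lower coordinate.

**NET-seq** (`netnuc`).  Read 3′ ends are extended 20 bp in the 5′
direction *inclusive* of the 3′ base (21-base footprint), a choice made
so coverage-mass conservation is exact; reads are sense when their
strand matches the anchor orientation, and telomeric anchors are
discarded.  The aborted-transcript score counts antisense 3′ ends in
`[anchor − 50, anchor]` (oriented) per 10³ in-window reads; 50 bp is the
operational width for "terminating at the binding site".  The cluster-4
split is the exact optimal 1-D two-means partition (contiguous in sorted
order, found by a prefix-sum scan), deterministic by construction; the
higher-score group is 4a.  An all-equal score vector refuses to split.

**Nucleosome shifts.**  Occupancy is the sum of fragment centers
extended ± 25 bp (51 bases).  Per side window (defaults `[−250, −50]`
and `[+50, +250]` oriented), the shift is the displacement of the
occupancy argmax, signed so negative = toward the binding site
(`|after| − |before|`).  Argmax is robust at the simulated scale; a flat
side window yields an undefined, flagged shift.

## Synthetic chromatin generator

The generator (`simulate`) is first-class, tested code and defines the
study conditions for all recovery tests.  A single synthetic chromosome
carries `n_sites_per_class` sites per promoter class (default 50),
spaced 3 kb ± 200 bp (min pairwise distance ≥ 2.6 kb), with 1 kb
telomere intervals at both ends.  Each site has a motif center, a random
motif strand, and a TSS fixed 120 bp away in a random direction (real
promoters show a preferred factor–TSS distance; a single fixed offset
keeps the geometry interpretable).

ChIP fragments are drawn per site from a four-component mixture:

| kind        | length model                                | placement |
|-------------|---------------------------------------------|-----------|
| tf_only     | 30 bp footprint + per-end overhang `floor(|N(0, sd/mnase)|)` | centered on motif |
| cobound     | `TruncNormal(190, 12)` on [160, 220]        | motif + one flanking nucleosome; TSS-distal side with prob 0.9 (C4) / 0.5 (others) |
| midfrag     | `N(150, 10)`                                | centered on motif |
| nucleosomal | `N(147, 5)`                                 | phased dyads at oriented ±150, ±315 |

Class mixture templates at unit MNase: C1 = 0.75/0.05/0.05/0.15
(tf/cobound/mid/nucleosomal), C2 = 0.45/0.05/0.35/0.15,
C3 = 0.40/0.30/0.05/0.25, C4a = C4b = 0.25/0.55/0.05/0.15.  The C2
"continuum" composition is a modeling choice — the class is described
qualitatively, not parameterized.  The mid-fragment weight scales as
`1/mnase_level` before renormalization: a simple monotone law
implementing the observation that these weakly protected fragments all
but vanish at high digestion.  Boundary noise defaults to sd 10 bp at
unit MNase, giving a modal short-fragment length near 46 bp (matching
the ~50 bp short class in real data) while keeping the modal fragment
boundary exactly at the protection edge: the overhang uses the *floor*
of the half-normal, whose zero bin is always modal, so footprint
recovery is exact whenever boundary noise is low (sd ≲ 1 effective).

NET-seq reads per site are sense (3′ ends 1–400 bp downstream of the
TSS) or antisense: C1 splits 50/50 with antisense mirrored around the
motif (symmetric initiation); C2/C3 are 70/30; C4a's antisense component
(weight 0.3) consists of aborted transcripts with 3′ ends within 50 bp
upstream of the motif; C4b's (0.3) initiates from a second NDR, 3′ ends
at −350 to −600.  Nucleosome fragments place the −1 dyad at oriented
−150 (C4b: pushed to −90) and the +1 at +250, with 12 bp positional
fuzziness (typical of MNase maps; it also makes the extended-center
occupancy unimodal at the dyad so the argmax estimator is unbiased).
Depletion of the remodeler moves the +1 dyad toward the motif by
`shift_bp` in every class; the −1 moves toward the motif for C1–C3,
stays fixed for C4a (locked), and moves away for C4b (pushed).

What the generator does *not* emulate: sequence (no FASTQ, no MNase
sequence bias, no real genome composition), mappability, replicate
structure, cross-linking-site preference, and continuous variation
between promoter classes (classes are discrete mixtures).  Passing
recovery tests therefore show that the operators are correct and
well-calibrated under the stated statistical structure, not that real
libraries satisfy that structure.

## Problem sizes and determinism

Recovery tests run at 50 sites/class × 500 fragments/site (clustering,
subclustering, asymmetry), 5,000 TF-only fragments (footprint), and
1,000 fragments/site per condition (shifts) — sizes at which every
recovery criterion is met with margin while the full suite runs in
seconds.  All randomness flows through `numpy.random.default_rng`
seeds carried in the parameter objects; identical seeds give bitwise
identical outputs, and the pipeline summary is byte-identical across
reruns.

## Known limitations

* Whether duplicate or multi-mapping templates should be removed is
  left to the caller (default: keep all); the ingest cap on template
  length (2,000 bp) mirrors the aligner setting.
* The canonical cluster ordering may transpose the two middle clusters
  relative to a continuum-vs-bimodal ordering.
* `nucleosome_shift` reports argmax displacement; a cross-correlation
  estimator would be preferable for noisy, low-coverage side windows.
* The background sampler ignores mappability (synthetic genomes are
  fully mappable).
* Three-way peak matching can chain A–B and B–C matches into one
  component even when A and C are > 64 bp apart; this is inherent to
  any component-based multiway extension of a pairwise rule.
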