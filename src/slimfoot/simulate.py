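"""Synthetic chromatin simulator with known ground truth.

Generates ChIP fragments, NET-seq 3'-end reads and nucleosome (MNase-seq)
fragments around parameterized promoter architectures.  Each binding site
belongs to one of five configuration classes mirroring the promoter classes
seen in fragment-length clustering of real factor-bound sites:

* **C1** — isolated factor binding: short (~30-50 bp) protected fragments
  dominate; transcription initiates symmetrically on both sides.
* **C2** — a continuum of factor-only and mid-length (~150 bp) weakly
  protected fragments; the mid-length component is MNase-sensitive.
* **C3** — bimodal: factor-only plus factor+nucleosome co-bound fragments
  with no side preference.
* **C4a** — bimodal with a strong preference for the TSS-distal (-1)
  nucleosome; the -1 nucleosome is *locked* (remodeler-insensitive) and
  short aborted antisense transcripts terminate at the binding site.
* **C4b** — like C4a but the -1 nucleosome is *pushed* against the factor
  by the remodeler (slides away on depletion) and antisense initiation
  happens from a separate NDR ~350 bp upstream instead.

Every emitted fragment/read is tagged ``site_id:class`` so downstream
recovery tests can score classification against ground truth.

Coordinate conventions: "oriented" offsets are measured from the motif
center with the nearest-TSS direction as +; the TSS sits at a fixed
+`tss_distance` (default 120 bp).  TSS-distal ("upstream") is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fragio import FragmentSet, StrandedReadSet

CLASSES = ("C1", "C2", "C3", "C4a", "C4b")

#: Fragment-class mixture templates at unit MNase, one per site class.
#: tf_only: the factor's own footprint; cobound: factor + one adjacent
#: nucleosome (160-220 bp); midfrag: ~150 bp weakly protected DNA around
#: the site; nucleosomal: phased flanking nucleosomes.
CLASS_WEIGHTS: dict[str, dict[str, float]] = {
    "C1": {"tf_only": 0.75, "cobound": 0.05, "midfrag": 0.05, "nucleosomal": 0.15},
    "C2": {"tf_only": 0.45, "cobound": 0.05, "midfrag": 0.35, "nucleosomal": 0.15},
    "C3": {"tf_only": 0.40, "cobound": 0.30, "midfrag": 0.05, "nucleosomal": 0.25},
    "C4a": {"tf_only": 0.25, "cobound": 0.55, "midfrag": 0.05, "nucleosomal": 0.15},
    "C4b": {"tf_only": 0.25, "cobound": 0.55, "midfrag": 0.05, "nucleosomal": 0.15},
}

FRAGMENT_KINDS = ("tf_only", "cobound", "midfrag", "nucleosomal")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic chromatin generator.

    mnase_level follows the relative 1x/9x/27x digestion scale: boundary
    overhangs shrink and the mid-length unprotected component fades as the
    level rises.
    """

    n_sites_per_class: int = 50
    fragments_per_site: int = 500
    mnase_level: float = 1.0
    boundary_noise_sd: float = 10.0          # bp, per fragment end at unit MNase
    protected_halfwidth: int = 15            # 30-bp footprint
    nucleosome_length: int = 147
    cobound_length_mean: float = 190.0
    cobound_length_sd: float = 12.0
    cobound_length_bounds: tuple[int, int] = (160, 220)
    midfrag_weight_at_unit_mnase: float = 1.0
    distal_side_prob: dict[str, float] = field(
        default_factory=lambda: {"C1": 0.5, "C2": 0.5, "C3": 0.5, "C4a": 0.9, "C4b": 0.9}
    )
    tss_distance: int = 120                  # bp downstream of motif center
    site_spacing: int = 3000                 # >= 2 kb guaranteed
    seed: int = 0

    def __post_init__(self):
        if self.mnase_level <= 0:
            raise ValueError("mnase_level must be positive")
        if self.boundary_noise_sd < 0:
            raise ValueError("boundary_noise_sd must be non-negative")
        if not 0 <= self.midfrag_weight_at_unit_mnase <= 1:
            raise ValueError("midfrag_weight_at_unit_mnase must be in [0,1]")
        for cls, p in self.distal_side_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"distal_side_prob[{cls}] outside [0,1]")
        if self.protected_halfwidth <= 0 or self.nucleosome_length <= 0:
            raise ValueError("lengths must be positive")
        lo, hi = self.cobound_length_bounds
        if not lo < hi:
            raise ValueError("cobound_length_bounds must be increasing")
        if self.site_spacing < 2000:
            raise ValueError("site_spacing must be >= 2000")

    def mixture_weights(self, class_label: str) -> dict[str, float]:
        """Effective fragment-class weights at this MNase level.

        The mid-length component is scaled by 1/mnase_level (monotone decay:
        at high digestion the weakly protected ~150 bp DNA is consumed),
        then the mixture is renormalized.
        """
        w = dict(CLASS_WEIGHTS[class_label])
        w["midfrag"] *= self.midfrag_weight_at_unit_mnase / self.mnase_level
        total = sum(w.values())
        return {k: v / total for k, v in w.items()}


@dataclass(frozen=True)
class SiteConfig:
    site_id: str
    chrom: str
    motif_center: int
    motif_strand: str
    tss_offset: int       # signed, relative to motif center
    tss_strand: str
    class_label: str

    @property
    def tss_pos(self) -> int:
        return self.motif_center + self.tss_offset

    @property
    def tss_sign(self) -> int:
        """+1 if the nearest-TSS direction is genomic plus."""
        return 1 if self.tss_offset >= 0 else -1


@dataclass
class SitePanel:
    """Simulator ground truth: sites, chromosome sizes, telomeres."""

    sites: list[SiteConfig]
    chrom_sizes: dict[str, int]
    telomeres: pd.DataFrame   # chrom, start, end

    def __post_init__(self):
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_ids must be unique")
        for s in self.sites:
            if not 0 <= s.motif_center < self.chrom_sizes[s.chrom]:
                raise ValueError(f"site {s.site_id} outside chromosome bounds")

    def __len__(self) -> int:
        return len(self.sites)

    def by_class(self, *labels: str) -> list[SiteConfig]:
        return [s for s in self.sites if s.class_label in labels]

    def anchors(self) -> pd.DataFrame:
        """TSS-oriented anchors at motif centers (one per site)."""
        return pd.DataFrame({
            "chrom": [s.chrom for s in self.sites],
            "pos": [s.motif_center for s in self.sites],
            "strand": [s.tss_strand for s in self.sites],
            "name": [s.site_id for s in self.sites],
            "class_label": [s.class_label for s in self.sites],
        })

    def to_tsv(self, path) -> None:
        pd.DataFrame([vars(s) | {"tss_pos": s.tss_pos} for s in self.sites]).to_csv(
            path, sep="\t", index=False)


def build_site_panel(params: SimulationParams) -> SitePanel:
    """Lay out a single synthetic chromosome of non-overlapping sites.

    Sites are spaced ``site_spacing`` apart (plus +-200 bp jitter, so minimum
    pairwise distance stays >= 2 kb at the default 3 kb spacing), class labels
    are shuffled across positions, and each site's TSS is placed
    ``tss_distance`` bp from the motif center in a random direction.
    """
    rng = np.random.default_rng(params.seed)
    n_total = params.n_sites_per_class * len(CLASSES)
    margin = 2000
    chrom = "chrS"
    chrom_size = 2 * margin + n_total * params.site_spacing
    telo = pd.DataFrame({"chrom": [chrom, chrom],
                         "start": [0, chrom_size - 1000],
                         "end": [1000, chrom_size]})

    labels = np.repeat(CLASSES, params.n_sites_per_class)
    rng.shuffle(labels)
    jitter = rng.integers(-200, 201, size=n_total)
    centers = margin + np.arange(n_total) * params.site_spacing + jitter
    if centers[-1] + margin > chrom_size:
        raise ValueError("chromosome too small for requested sites")
    motif_strands = rng.choice(["+", "-"], size=n_total)
    tss_signs = rng.choice([1, -1], size=n_total)

    sites = [
        SiteConfig(
            site_id=f"site{i:04d}",
            chrom=chrom,
            motif_center=int(centers[i]),
            motif_strand=str(motif_strands[i]),
            tss_offset=int(tss_signs[i]) * params.tss_distance,
            tss_strand="+" if tss_signs[i] > 0 else "-",
            class_label=str(labels[i]),
        )
        for i in range(n_total)
    ]
    return SitePanel(sites=sites, chrom_sizes={chrom: chrom_size}, telomeres=telo)


# ---------------------------------------------------------------------------
# ChIP fragments
# ---------------------------------------------------------------------------

def _rounded_halfnormal(rng, sd: float, size: int) -> np.ndarray:
    # floor of the half-normal: the zero-overhang bin is always the modal
    # one, so the modal fragment boundary sits exactly at the protection
    # edge at every noise level
    return np.floor(np.abs(rng.normal(0.0, sd, size=size))).astype(np.int64)


def simulate_chip_fragments(panel: SitePanel, params: SimulationParams,
                            seed: int | None = None) -> FragmentSet:
    """Draw ChIP fragments from each site's class mixture.

    Per fragment kind (oriented coordinates, TSS direction = +):

    * ``tf_only`` spans the protected region [-h, +h) plus an independent
      half-normal outward overhang on each end with sd
      ``boundary_noise_sd / mnase_level`` — sharp modal boundaries exactly
      at the protection edges.
    * ``cobound`` has length ~ TruncNormal(190, 12) on [160, 220] and covers
      the motif plus one adjacent nucleosome; the nucleosome side is
      TSS-distal with probability ``distal_side_prob[class]``.
    * ``midfrag`` has length ~ Normal(150, 10) centered on the motif; its
      mixture weight decays as 1/mnase_level.
    * ``nucleosomal`` has length ~ Normal(147, 5) at phased dyads flanking
      the NDR (oriented +-150, +-315).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    h = params.protected_halfwidth
    sd_end = params.boundary_noise_sd / params.mnase_level
    lo, hi = params.cobound_length_bounds
    a = (lo - params.cobound_length_mean) / params.cobound_length_sd
    b = (hi - params.cobound_length_mean) / params.cobound_length_sd

    chroms, starts, ends, names = [], [], [], []
    for site in panel.sites:
        n = params.fragments_per_site
        w = params.mixture_weights(site.class_label)
        kinds = rng.choice(FRAGMENT_KINDS, size=n, p=[w[k] for k in FRAGMENT_KINDS])
        olo = np.empty(n, dtype=np.int64)   # oriented start (inclusive)
        ohi = np.empty(n, dtype=np.int64)   # oriented end (exclusive)

        m = kinds == "tf_only"
        if m.any():
            k = int(m.sum())
            o5 = _rounded_halfnormal(rng, sd_end, k)
            o3 = _rounded_halfnormal(rng, sd_end, k)
            olo[m] = -h - o5
            ohi[m] = h + o3

        m = kinds == "cobound"
        if m.any():
            k = int(m.sum())
            length = np.clip(np.rint(stats.truncnorm.rvs(
                a, b, loc=params.cobound_length_mean,
                scale=params.cobound_length_sd, size=k, random_state=rng)), lo, hi
            ).astype(np.int64)
            distal = rng.random(k) < params.distal_side_prob.get(site.class_label, 0.5)
            edge = h + _rounded_halfnormal(rng, sd_end, k)
            # distal: nucleosome on the TSS-distal (negative) side, fragment
            # inner edge just past the motif on the TSS side; proximal mirrors.
            ohi[m] = np.where(distal, edge, -edge + length)
            olo[m] = np.where(distal, edge - length, -edge)

        m = kinds == "midfrag"
        if m.any():
            k = int(m.sum())
            length = np.maximum(np.rint(rng.normal(150, 10, size=k)), 40).astype(np.int64)
            olo[m] = -(length // 2)
            ohi[m] = olo[m] + length

        m = kinds == "nucleosomal"
        if m.any():
            k = int(m.sum())
            dyads = rng.choice([-315, -150, 150, 315], size=k, p=[0.15, 0.35, 0.35, 0.15])
            centers = dyads + np.rint(rng.normal(0, 3, size=k)).astype(np.int64)
            length = np.maximum(np.rint(rng.normal(params.nucleosome_length, 5, size=k)), 80
                                ).astype(np.int64)
            olo[m] = centers - length // 2
            ohi[m] = olo[m] + length

        sign = site.tss_sign
        if sign > 0:
            gstart = site.motif_center + olo
            gend = site.motif_center + ohi
        else:
            gstart = site.motif_center - ohi + 1
            gend = site.motif_center - olo + 1
        chroms.extend([site.chrom] * n)
        starts.append(gstart)
        ends.append(gend)
        names.extend(f"{site.site_id}:{site.class_label}|{k}" for k in kinds)

    frags = pd.DataFrame({
        "chrom": chroms,
        "start": np.concatenate(starts),
        "end": np.concatenate(ends),
        "name": names,
        "strand": ".",
    })
    return FragmentSet(frags, dict(panel.chrom_sizes))


def fragment_kind(fs: FragmentSet) -> pd.Series:
    """Ground-truth fragment kind from ``site:class|kind`` names."""
    return fs.frags["name"].str.rsplit("|", n=1).str[-1]


# ---------------------------------------------------------------------------
# NET-seq reads
# ---------------------------------------------------------------------------

def simulate_netseq_reads(panel: SitePanel, reads_per_site: int, seed: int,
                          aborted_weight: float = 0.3) -> StrandedReadSet:
    """Simulate strand-resolved NET-seq 3'-end positions per site.

    Sense reads (in the nearest-TSS direction) pile downstream of the TSS
    for every class.  Antisense behaviour is class-specific:

    * C1 — initiation is symmetric: half of the reads are antisense,
      mirrored around the motif.
    * C2/C3 — bidirectional with a sense preference (30% antisense).
    * C4a — no upstream initiation, but ``aborted_weight`` of the reads are
      short aborted antisense transcripts whose 3' ends terminate within
      50 bp upstream of the motif center.
    * C4b — no aborted transcripts; 30% of reads initiate from a separate
      NDR ~350 bp upstream of the binding site (3' ends upstream of -350).
    """
    if not 0 <= aborted_weight <= 1:
        raise ValueError("aborted_weight must be in [0,1]")
    rng = np.random.default_rng(seed)
    antisense_frac = {"C1": 0.5, "C2": 0.3, "C3": 0.3, "C4a": aborted_weight, "C4b": 0.3}

    chroms, poss, strands, names = [], [], [], []
    for site in panel.sites:
        n = reads_per_site
        cls = site.class_label
        is_anti = rng.random(n) < antisense_frac[cls]
        n_anti = int(is_anti.sum())
        offsets = np.empty(n, dtype=np.int64)
        # sense: 3' ends downstream of the TSS (elongating Pol II)
        offsets[~is_anti] = np.abs(site.tss_offset) + rng.integers(1, 401, size=n - n_anti)
        if cls in ("C1", "C2", "C3"):
            # divergent initiation mirrored on the upstream side
            offsets[is_anti] = -(np.abs(site.tss_offset) + rng.integers(1, 401, size=n_anti))
        elif cls == "C4a":
            # aborted transcripts terminating at the binding site
            offsets[is_anti] = -rng.integers(0, 51, size=n_anti)
        else:  # C4b: upstream-NDR initiation ~350 bp upstream
            offsets[is_anti] = -350 - rng.integers(0, 251, size=n_anti)

        sign = site.tss_sign
        gpos = site.motif_center + sign * offsets
        sense_strand = site.tss_strand
        anti_strand = "-" if sense_strand == "+" else "+"
        chroms.extend([site.chrom] * n)
        poss.append(gpos)
        strands.extend(np.where(is_anti, anti_strand, sense_strand))
        names.extend([f"{site.site_id}:{cls}"] * n)

    reads = pd.DataFrame({
        "chrom": chroms, "pos": np.concatenate(poss),
        "strand": strands, "name": names,
    })
    return StrandedReadSet(reads, dict(panel.chrom_sizes))


# ---------------------------------------------------------------------------
# Nucleosome (MNase-seq) fragments
# ---------------------------------------------------------------------------

#: Oriented dyad positions of the -1 (TSS-distal) and +1 (TSS-proximal,
#: past the TSS) nucleosomes.  The C4b -1 dyad sits pushed against the
#: motif edge.
BASE_DYADS = {"minus1": -150, "plus1": 250}
C4B_PUSHED_MINUS1 = -90


def nucleosome_dyads(class_label: str, depleted: bool, shift_bp: int) -> dict[str, int]:
    """Oriented -1/+1 dyad positions for a class, before/after depletion.

    Depletion of the remodeler moves nucleosomes into the NDR (toward the
    motif) for C1-like promoters; the C4a -1 nucleosome is locked in place,
    and the C4b -1 (normally pushed against the factor) slides away.
    """
    minus1 = C4B_PUSHED_MINUS1 if class_label == "C4b" else BASE_DYADS["minus1"]
    plus1 = BASE_DYADS["plus1"]
    if depleted:
        plus1 -= shift_bp                       # +1 moves toward the motif, all classes
        if class_label == "C4a":
            pass                                # locked -1
        elif class_label == "C4b":
            minus1 -= shift_bp                  # slides away from the motif
        else:
            minus1 += shift_bp                  # into the NDR, toward the motif
    return {"minus1": minus1, "plus1": plus1}


def simulate_nucleosome_fragments(panel: SitePanel, depleted: bool, shift_bp: int,
                                  seed: int, fragments_per_site: int = 1000) -> FragmentSet:
    """MNase-seq-style nucleosomal fragments at the -1/+1 dyads."""
    if shift_bp < 0:
        raise ValueError("shift_bp must be >= 0")
    rng = np.random.default_rng(seed)
    chroms, starts, ends, names = [], [], [], []
    for site in panel.sites:
        n = fragments_per_site
        dyads = nucleosome_dyads(site.class_label, depleted, shift_bp)
        side = rng.choice(["minus1", "plus1"], size=n)
        dyad = np.where(side == "minus1", dyads["minus1"], dyads["plus1"])
        # positional fuzziness ~12 bp sd, typical of MNase nucleosome maps;
        # makes the center-extended occupancy unimodal at the dyad rather
        # than a flat plateau, so the occupancy argmax estimates the dyad
        centers = dyad + np.rint(rng.normal(0, 12, size=n)).astype(np.int64)
        length = np.maximum(np.rint(rng.normal(147, 5, size=n)), 80).astype(np.int64)
        olo = centers - length // 2
        ohi = olo + length
        if site.tss_sign > 0:
            gstart, gend = site.motif_center + olo, site.motif_center + ohi
        else:
            gstart, gend = site.motif_center - ohi + 1, site.motif_center - olo + 1
        chroms.extend([site.chrom] * n)
        starts.append(gstart)
        ends.append(gend)
        names.extend(f"{site.site_id}:{site.class_label}|{s}" for s in side)

    frags = pd.DataFrame({
        "chrom": chroms, "start": np.concatenate(starts),
        "end": np.concatenate(ends), "name": names, "strand": ".",
    })
    return FragmentSet(frags, dict(panel.chrom_sizes))
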